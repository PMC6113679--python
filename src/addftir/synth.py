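"""Deterministic generators of synthetic polymer spectra, reference
libraries, and particle-laden imaging cubes with exact ground truth.

Pseudo-polymer spectra are Gaussian band mixtures — a deliberate
idealization that keeps every downstream stage (baseline correction,
Hellinger clustering, dual-correlation search, particle measurement)
testable without measured data. Scenes place particles of chosen polymers
on an empty filter, add an optional weak broad background band (emulating
the Si-O-H stretch of diatom shells in the 3200-3600 cm^-1 window),
per-pixel linear baseline drift and Gaussian noise, and can clip thick
particles at a detector saturation cap. Every generator is a pure function
of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import hellinger_matrix
from .matching import HyperspectralCube
from .preprocess import percent_normalize
from .spectra import (
    AcquisitionMethod,
    ClusterDefinition,
    ReferenceLibrary,
    Spectrum,
    SpectrumMetadata,
    WavenumberGrid,
)

__all__ = [
    "BandSpec",
    "ParticleSpec",
    "SceneSpec",
    "default_imaging_grid",
    "synth_spectrum",
    "synth_library",
    "apply_saturation",
    "synth_cube",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band."""

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    height: float  # absorbance

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("band width and height must be positive")


@dataclass(frozen=True)
class ParticleSpec:
    """A particle to paint into a scene.

    ``shape`` is "rect" (height x width pixels) or "disk" (radius pixels),
    anchored at ``position`` (top-left for rect, center for disk).
    ``thickness`` scales absorbance linearly (Beer-Lambert idealization).
    """

    polymer_id: str
    position: tuple[int, int]
    shape: str = "rect"
    size: tuple[int, int] | int = (3, 3)
    thickness: float = 1.0

    def mask_coords(self, shape: tuple[int, int]) -> np.ndarray:
        r, c = self.position
        if self.shape == "rect":
            h, w = self.size if isinstance(self.size, tuple) else (self.size, self.size)
            coords = [(r + i, c + j) for i in range(h) for j in range(w)]
        elif self.shape == "disk":
            rad = int(self.size) if not isinstance(self.size, tuple) else int(self.size[0])
            coords = [
                (r + i, c + j)
                for i in range(-rad, rad + 1)
                for j in range(-rad, rad + 1)
                if i * i + j * j <= rad * rad
            ]
        else:
            raise ValueError(f"unknown particle shape {self.shape!r}")
        out = np.asarray(coords)
        if (
            out[:, 0].min() < 0
            or out[:, 1].min() < 0
            or out[:, 0].max() >= shape[0]
            or out[:, 1].max() >= shape[1]
        ):
            raise ValueError("particle extends outside the scene")
        return out


@dataclass(frozen=True)
class SceneSpec:
    """A synthetic imaging scene with exact ground truth."""

    shape: tuple[int, int]
    particles: tuple[ParticleSpec, ...]
    pixel_pitch: float = 11.0
    background_bands: tuple[BandSpec, ...] = ()
    noise_sigma: float = 0.0
    drift_amplitude: float = 0.0  # max |offset| of the per-pixel linear tilt
    saturation_cap: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "particles", tuple(self.particles))
        object.__setattr__(self, "background_bands", tuple(self.background_bands))


def default_imaging_grid(
    lo: float = 1250.0, hi: float = 3600.0, step: float = 8.0
) -> WavenumberGrid:
    """Imaging wavenumber grid, descending, 8 cm^-1 spacing by default."""
    return WavenumberGrid(np.arange(hi, lo - 1e-9, -step))


def synth_spectrum(
    bands: Sequence[BandSpec],
    grid: WavenumberGrid,
    name: str = "synthetic",
    method: AcquisitionMethod = AcquisitionMethod.ATR,
) -> Spectrum:
    """Sum of Gaussian bands evaluated on the grid."""
    wn = grid.values
    y = np.zeros(len(grid))
    for b in bands:
        y += b.height * np.exp(-0.5 * ((wn - b.center) / b.width) ** 2)
    return Spectrum(
        grid=grid,
        intensities=y,
        metadata=SpectrumMetadata(sample_name=name, method=method, form="synthetic"),
    )


#: band centers are kept clear of the CO2/artifact replacement window so
#: synthetic polymers lose no diagnostic band to the straight-line step
_EXCLUDED_CENTER_RANGE = (2150.0, 2500.0)


def _draw_bands(
    rng: np.random.Generator, n_bands: int, lo: float, hi: float
) -> list[BandSpec]:
    margin = 0.05 * (hi - lo)
    centers = []
    while len(centers) < n_bands:
        c = rng.uniform(lo + margin, hi - margin)
        if not _EXCLUDED_CENTER_RANGE[0] <= c <= _EXCLUDED_CENTER_RANGE[1]:
            centers.append(c)
    widths = rng.uniform(15.0, 45.0, size=n_bands)
    heights = rng.uniform(0.3, 1.0, size=n_bands)
    return [BandSpec(c, w, h) for c, w, h in zip(centers, widths, heights)]


def synth_library(
    n_polymers: int,
    bands_per_polymer: int = 4,
    grid: WavenumberGrid | None = None,
    seed: int = 0,
    min_hellinger: float = 0.5,
    max_draws: int = 200,
) -> ReferenceLibrary:
    """Reference library of distinct pseudo-polymers, one cluster each.

    Entries are percent-normalized band mixtures; candidate polymers are
    redrawn until all pairwise Hellinger distances reach ``min_hellinger``,
    so the library is genuinely separable by the downstream search.
    """
    if n_polymers < 1:
        raise ValueError("need at least one polymer")
    grid = grid or default_imaging_grid()
    lo, hi = grid.extent
    rng = np.random.default_rng(seed)
    kept: list[list[BandSpec]] = []
    rows: list[np.ndarray] = []
    draws = 0
    while len(kept) < n_polymers:
        if draws >= max_draws:
            raise RuntimeError(
                f"could not draw {n_polymers} polymers with pairwise Hellinger "
                f">= {min_hellinger} in {max_draws} attempts"
            )
        draws += 1
        bands = _draw_bands(rng, bands_per_polymer, lo, hi)
        cand = synth_spectrum(bands, grid).intensities
        if rows:
            d = hellinger_matrix(np.vstack([np.stack(rows), cand[None]]))[-1, :-1]
            if d.min() < min_hellinger:
                continue
        kept.append(bands)
        rows.append(cand)
    entries: dict[str, Spectrum] = {}
    clusters: list[ClusterDefinition] = []
    for k, bands in enumerate(kept):
        sid = f"polymer_{k + 1:02d}"
        spec = synth_spectrum(bands, grid, name=sid)
        entries[sid] = percent_normalize(spec)
        clusters.append(ClusterDefinition(k + 1, sid, {sid}))
    return ReferenceLibrary(
        grid=grid, entries=entries, clusters=clusters, spectral_range=grid.extent
    )


def apply_saturation(spectrum: Spectrum, cap: float) -> Spectrum:
    """Clip absorbance at the detection limit (thick-particle total absorbance).

    Above the cap the measured values carry no information about the rest of
    the band structure — characteristic bands flatten out.
    """
    if cap < 0:
        raise ValueError("saturation cap must be >= 0")
    return spectrum.with_intensities(np.minimum(spectrum.intensities, cap))


def synth_cube(
    scene: SceneSpec, library: ReferenceLibrary
) -> tuple[HyperspectralCube, np.ndarray, list[dict]]:
    """Render a scene into a cube plus exact ground truth.

    Returns ``(cube, truth_map, truth_particles)``: ``truth_map`` holds the
    true cluster number per pixel (0 = background), ``truth_particles`` one
    record per placed particle (cluster number, pixel count, coordinates).
    Pixel spectra are polymer entry x thickness + background + per-pixel
    linear drift + Gaussian noise, optionally clipped at the saturation cap.
    """
    grid = library.grid
    nr, nc = scene.shape
    nw = len(grid)
    rng = np.random.default_rng(scene.seed)
    data = np.zeros((nr, nc, nw))
    truth = np.zeros((nr, nc), dtype=int)
    truth_particles: list[dict] = []
    if scene.background_bands:
        bg = synth_spectrum(scene.background_bands, grid).intensities
        data += bg[None, None, :]
    for spec in scene.particles:
        if spec.polymer_id not in library.entries:
            raise ValueError(f"unknown polymer id {spec.polymer_id!r}")
        cnum = library.cluster_of(spec.polymer_id)
        coords = spec.mask_coords(scene.shape)
        profile = library.entries[spec.polymer_id].intensities * spec.thickness
        for r, c in coords:
            data[r, c] += profile
            truth[r, c] = cnum
        truth_particles.append(
            {
                "polymer_id": spec.polymer_id,
                "cluster_number": int(cnum),
                "pixel_count": int(len(coords)),
                "coords": coords,
            }
        )
    if scene.drift_amplitude > 0:
        x = np.linspace(-0.5, 0.5, nw)
        offs = rng.uniform(-scene.drift_amplitude, scene.drift_amplitude, (nr, nc, 1))
        slope = rng.uniform(-scene.drift_amplitude, scene.drift_amplitude, (nr, nc, 1))
        data += offs + slope * x[None, None, :]
    if scene.noise_sigma > 0:
        data += rng.normal(0.0, scene.noise_sigma, size=data.shape)
    if scene.saturation_cap is not None:
        data = np.minimum(data, scene.saturation_cap)
    cube = HyperspectralCube(
        data=data,
        grid=grid,
        pixel_pitch=scene.pixel_pitch,
        acquisition_meta=f"synthetic scene, seed={scene.seed}",
    )
    return cube, truth, truth_particles
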