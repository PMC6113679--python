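"""Pixel-wise identification of hyperspectral FTIR cubes.

Every pixel spectrum is searched twice against the reference library: once
as a database-preprocessed raw spectrum and once as the vector-normalized
first derivative. Each search scores entries by non-negative Pearson
correlation (hit quality). A pixel counts as identified only when both
searches agree on the cluster AND both hit qualities clear their
thresholds — the agreement rule that keeps single-channel coincidences out
of the particle statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .preprocess import (
    PreprocessConfig,
    clip_negatives,
    database_preprocess,
    first_derivative,
    percent_normalize,
    replace_region_with_line,
    rubberband_baseline,
    vector_normalize,
)
from .spectra import (
    AcquisitionMethod,
    ReferenceLibrary,
    Spectrum,
    SpectrumMetadata,
    WavenumberGrid,
    crop_range,
)

__all__ = [
    "HyperspectralCube",
    "MatchConfig",
    "SearchResult",
    "SearchLibrary",
    "PixelAssignmentMap",
    "UNASSIGNED",
    "prepare_search_libraries",
    "correlation_hit_quality",
    "search_spectrum",
    "identify_pixels",
    "mask_region",
]

#: cluster number reserved for unidentified pixels
UNASSIGNED = 0


@dataclass
class HyperspectralCube:
    """Row-major pixel grid of spectra with a physical pixel pitch in um."""

    data: np.ndarray  # (rows, cols, n_wavenumbers)
    grid: WavenumberGrid
    pixel_pitch: float = 11.0
    acquisition_meta: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != len(self.grid):
            raise ValueError("cube data must be (rows, cols, len(grid))")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        self.data = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(
            grid=self.grid,
            intensities=self.data[row, col],
            metadata=SpectrumMetadata(
                sample_name=f"pixel({row},{col})",
                method=AcquisitionMethod.TRANSMISSION,
            ),
        )

    def save(self, directory: str | Path) -> Path:
        """Write as little-endian float32 row-major binary + JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "cube.f32").write_bytes(
            np.ascontiguousarray(self.data, dtype="<f4").tobytes()
        )
        sidecar = {
            "shape": list(self.data.shape),
            "wavenumbers": self.grid.values.tolist(),
            "pixel_pitch_um": self.pixel_pitch,
            "acquisition_meta": self.acquisition_meta,
            "dtype": "<f4",
            "order": "row-major",
        }
        (directory / "cube.json").write_text(json.dumps(sidecar))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "HyperspectralCube":
        directory = Path(directory)
        sidecar = json.loads((directory / "cube.json").read_text())
        raw = np.frombuffer((directory / "cube.f32").read_bytes(), dtype="<f4")
        data = raw.reshape(sidecar["shape"]).astype(float)
        return cls(
            data=data,
            grid=WavenumberGrid(np.asarray(sidecar["wavenumbers"])),
            pixel_pitch=sidecar["pixel_pitch_um"],
            acquisition_meta=sidecar.get("acquisition_meta", ""),
        )


@dataclass(frozen=True)
class MatchConfig:
    """Thresholds and search range of the dual-correlation search."""

    threshold_raw: float = 0.6
    threshold_derivative: float = 0.6
    spectral_range: tuple[float, float] = (1250.0, 3600.0)

    def __post_init__(self) -> None:
        for t in (self.threshold_raw, self.threshold_derivative):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        lo, hi = self.spectral_range
        object.__setattr__(self, "spectral_range", (min(lo, hi), max(lo, hi)))


@dataclass(frozen=True)
class SearchResult:
    entry_id: str
    cluster_number: int
    hit_quality: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hit_quality <= 1.0:
            raise ValueError("hit_quality must lie in [0, 1]")


@dataclass(frozen=True)
class SearchLibrary:
    """One search variant: entries as rows of a matrix, aligned metadata."""

    grid: WavenumberGrid
    entry_ids: tuple[str, ...]
    cluster_numbers: np.ndarray
    matrix: np.ndarray  # (n_entries, len(grid))
    variant: str  # "raw" | "derivative"


def prepare_search_libraries(
    library: ReferenceLibrary,
    cfg: MatchConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
) -> tuple[SearchLibrary, SearchLibrary]:
    """Build the raw and derivative search variants of a reference library.

    Variant A crops each entry to the search range; variant B is the
    Savitzky-Golay first derivative followed by vector normalization.
    Entries whose derivative is identically zero (constant spectra) are
    excluded from both variants with a warning — they carry no band
    information to correlate against.
    """
    import warnings

    cfg = cfg or MatchConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    lo, hi = cfg.spectral_range
    glo, ghi = library.grid.extent
    # grid registration may leave no datapoint exactly at a range edge; allow
    # one grid step of slack, beyond that the range is genuinely uncovered
    step = (ghi - glo) / (len(library.grid) - 1)
    if lo < glo - step or hi > ghi + step:
        raise ValueError(
            f"search range [{lo}, {hi}] not covered by library grid [{glo}, {ghi}]"
        )
    ids, clusters, raw_rows, der_rows = [], [], [], []
    ref_grid: WavenumberGrid | None = None
    for sid in library.sorted_ids():
        cnum = library.cluster_of(sid)
        if cnum is None:
            continue  # unassigned pool takes no part in the search
        entry = crop_range(library.entries[sid], lo, hi)
        der = first_derivative(entry, pre_cfg)
        if np.allclose(der.intensities, 0.0):
            warnings.warn(
                f"entry {sid!r} has a zero derivative (constant spectrum); excluded",
                stacklevel=2,
            )
            continue
        ids.append(sid)
        clusters.append(cnum)
        raw_rows.append(entry.intensities)
        der_rows.append(vector_normalize(der).intensities)
        ref_grid = entry.grid
    if not ids:
        raise ValueError("no usable library entries in the search range")
    return (
        SearchLibrary(ref_grid, tuple(ids), np.asarray(clusters), np.stack(raw_rows), "raw"),
        SearchLibrary(ref_grid, tuple(ids), np.asarray(clusters), np.stack(der_rows), "derivative"),
    )


def correlation_hit_quality(a: np.ndarray, b: np.ndarray) -> float:
    """Non-negative Pearson correlation of two equal-length sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal lengths >= 3")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return max(r, 0.0)


def _best_hits(
    pixels: np.ndarray, lib: SearchLibrary
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized best-correlation search of pixel rows against library rows.

    Returns (entry index, cluster number, hit quality) per pixel row. Ties
    on quality break toward the lowest cluster number, then the
    lexicographically smallest entry id. Zero-variance pixels score 0.
    """
    L = lib.matrix - lib.matrix.mean(axis=1, keepdims=True)
    Lnorm = np.linalg.norm(L, axis=1)
    P = pixels - pixels.mean(axis=1, keepdims=True)
    Pnorm = np.linalg.norm(P, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (P @ L.T) / np.outer(Pnorm, Lnorm)
    R = np.where(np.isfinite(R), R, 0.0)
    Q = np.clip(R, 0.0, 1.0)
    # tie-break: sort order of entries by (cluster_number, entry_id); argmax
    # over entries arranged in that order returns the first maximum
    order = sorted(
        range(len(lib.entry_ids)),
        key=lambda i: (int(lib.cluster_numbers[i]), lib.entry_ids[i]),
    )
    order = np.asarray(order)
    Qo = Q[:, order]
    best = np.argmax(np.isclose(Qo, Qo.max(axis=1, keepdims=True), rtol=0, atol=1e-12), axis=1)
    entry_idx = order[best]
    quality = Q[np.arange(len(pixels)), entry_idx]
    return entry_idx, lib.cluster_numbers[entry_idx], quality


def search_spectrum(pixel: Spectrum | np.ndarray, variant_library: SearchLibrary) -> SearchResult:
    """Best library entry for one (already variant-preprocessed) spectrum."""
    values = pixel.intensities if isinstance(pixel, Spectrum) else np.asarray(pixel, float)
    if values.size != variant_library.matrix.shape[1]:
        raise ValueError("pixel spectrum is not on the library grid")
    idx, cnum, q = _best_hits(values[None], variant_library)
    return SearchResult(
        entry_id=variant_library.entry_ids[int(idx[0])],
        cluster_number=int(cnum[0]),
        hit_quality=float(q[0]),
    )


@dataclass
class PixelAssignmentMap:
    """Per-pixel cluster assignments plus both underlying search channels."""

    cluster: np.ndarray  # (rows, cols) int, UNASSIGNED where unidentified
    raw_cluster: np.ndarray
    raw_quality: np.ndarray
    derivative_cluster: np.ndarray
    derivative_quality: np.ndarray
    pixel_pitch: float
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.masked is None:
            self.masked = np.zeros(self.cluster.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cluster.shape

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.cluster != UNASSIGNED))

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "cluster_number": self.cluster.ravel(),
                "hq_raw": self.raw_quality.ravel(),
                "hq_deriv": self.derivative_quality.ravel(),
                "masked": self.masked.ravel(),
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def _preprocess_pixel_block(
    cube: HyperspectralCube, cfg: MatchConfig, pre_cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, WavenumberGrid]:
    """Raw-channel and derivative-channel matrices for every pixel.

    Raw channel: database chain without the SNR exclusion (pixels are never
    discarded, only left unassigned); imaging pixels are transmission
    measurements, so the CO2 band is line-replaced. Derivative channel:
    Savitzky-Golay derivative of the cropped pixel, vector-normalized.
    Returns (raw matrix, derivative matrix, validity mask, cropped grid).
    """
    nr, nc = cube.shape
    npix = nr * nc
    lo, hi = cfg.spectral_range
    flat = cube.data.reshape(npix, -1)

    template = cube.pixel(0, 0)
    cropped_tpl = crop_range(template, lo, hi)
    ncrop = len(cropped_tpl)
    raw = np.zeros((npix, ncrop))
    valid = np.ones(npix, dtype=bool)
    pre = replace(pre_cfg, spectral_range=(lo, hi))
    for i in range(npix):
        try:
            s = Spectrum(cube.grid, flat[i], template.metadata)
            raw[i] = database_preprocess(s, pre).intensities
        except ValueError:
            valid[i] = False  # e.g. all-zero pixel: nothing to normalize

    # derivative channel is batch-safe: savgol over the whole block at once
    from scipy.signal import savgol_filter

    keep = (cube.grid.values >= lo) & (cube.grid.values <= hi)
    delta = cropped_tpl.grid.spacing()
    der = savgol_filter(
        flat[:, keep][:, ::-1],
        window_length=pre.derivative_window,
        polyorder=pre.derivative_polyorder,
        deriv=1,
        delta=delta,
        mode="interp",
        axis=1,
    )[:, ::-1]
    norms = np.linalg.norm(der, axis=1, keepdims=True)
    flat_der = norms[:, 0] == 0
    valid &= ~flat_der
    der = np.divide(der, np.where(norms == 0, 1.0, norms))
    return raw, der, valid, cropped_tpl.grid


def identify_pixels(
    cube: HyperspectralCube,
    library: ReferenceLibrary,
    cfg: MatchConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
) -> PixelAssignmentMap:
    """Dual-correlation identification of every pixel under the agreement rule.

    A pixel is assigned the common cluster number only when the raw search
    and the derivative search find the same cluster and both hit qualities
    reach their thresholds; otherwise it stays ``UNASSIGNED``.
    """
    cfg = cfg or MatchConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    raw_lib, der_lib = prepare_search_libraries(library, cfg, pre_cfg)
    raw_px, der_px, valid, crop_grid = _preprocess_pixel_block(cube, cfg, pre_cfg)
    if raw_px.shape[1] != raw_lib.matrix.shape[1]:
        raise ValueError("cube grid does not match library grid on the search range")

    _, raw_cluster, raw_q = _best_hits(raw_px, raw_lib)
    _, der_cluster, der_q = _best_hits(der_px, der_lib)
    raw_q = np.where(valid, raw_q, 0.0)
    der_q = np.where(valid, der_q, 0.0)
    agree = (
        valid
        & (raw_cluster == der_cluster)
        & (raw_q >= cfg.threshold_raw)
        & (der_q >= cfg.threshold_derivative)
    )
    assigned = np.where(agree, raw_cluster, UNASSIGNED)
    nr, nc = cube.shape
    return PixelAssignmentMap(
        cluster=assigned.reshape(nr, nc).astype(int),
        raw_cluster=raw_cluster.reshape(nr, nc).astype(int),
        raw_quality=raw_q.reshape(nr, nc),
        derivative_cluster=der_cluster.reshape(nr, nc).astype(int),
        derivative_quality=der_q.reshape(nr, nc),
        pixel_pitch=cube.pixel_pitch,
    )


def mask_region(
    assignment: PixelAssignmentMap, region: Iterable[tuple[int, int]] | np.ndarray
) -> PixelAssignmentMap:
    """Blank out a pixel region (e.g. the filter's polypropylene support).

    ``region`` is a boolean mask of the map's shape or an iterable of
    (row, col) indices. Masked pixels become UNASSIGNED and stay flagged.
    """
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != assignment.shape:
            raise ValueError("mask shape mismatch")
        mask = region
    else:
        mask = np.zeros(assignment.shape, dtype=bool)
        for r, c in region:
            if not (0 <= r < assignment.shape[0] and 0 <= c < assignment.shape[1]):
                raise ValueError(f"pixel ({r}, {c}) outside the map")
            mask[r, c] = True
    new_cluster = np.where(mask, UNASSIGNED, assignment.cluster)
    return PixelAssignmentMap(
        cluster=new_cluster,
        raw_cluster=assignment.raw_cluster,
        raw_quality=assignment.raw_quality,
        derivative_cluster=assignment.derivative_cluster,
        derivative_quality=assignment.derivative_quality,
        pixel_pitch=assignment.pixel_pitch,
        masked=assignment.masked | mask,
    )
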