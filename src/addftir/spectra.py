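"""Core data model for FTIR spectra, reference libraries, and grid operations.

A :class:`Spectrum` couples a wavenumber grid (cm^-1, stored descending by
FTIR convention) with absorbance intensities and provenance metadata. A
:class:`ReferenceLibrary` is a set of spectra on one common grid, partitioned
into numbered clusters — the unit the automated pixel identification searches
against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AcquisitionMethod",
    "WavenumberGrid",
    "SpectrumMetadata",
    "Spectrum",
    "ClusterDefinition",
    "ReferenceLibrary",
    "resample_to_grid",
    "crop_range",
    "average_replicates",
]

#: grids closer than this (max |delta nu| in cm^-1) are treated as identical
GRID_TOLERANCE = 1e-6


class AcquisitionMethod(str, Enum):
    """How a reference spectrum was measured."""

    ATR = "ATR"
    TRANSMISSION = "transmission"


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly monotonic wavenumber axis in cm^-1, stored descending."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavenumber grid needs at least 2 points")
        if np.any(vals <= 0):
            raise ValueError("wavenumbers must be positive")
        d = np.diff(vals)
        if np.all(d > 0):
            vals = vals[::-1]  # normalize ascending input to FTIR convention
        elif not np.all(d < 0):
            raise ValueError("wavenumber grid must be strictly monotonic")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def extent(self) -> tuple[float, float]:
        """(lowest, highest) wavenumber covered."""
        return float(self.values[-1]), float(self.values[0])

    @property
    def ascending(self) -> np.ndarray:
        return self.values[::-1]

    def spacing(self) -> float:
        """Mean absolute grid step; raises if the grid is not uniform."""
        steps = -np.diff(self.values)
        if np.ptp(steps) > 1e-6 * steps.mean():
            raise ValueError("grid is not uniformly spaced")
        return float(steps.mean())

    def isclose(self, other: "WavenumberGrid") -> bool:
        return len(self) == len(other) and bool(
            np.max(np.abs(self.values - other.values)) < GRID_TOLERANCE
        )


@dataclass(frozen=True)
class SpectrumMetadata:
    """Infobox attached to every reference spectrum."""

    sample_name: str
    abbreviation: str = ""
    supplier: str = ""
    source_id: str = ""
    form: str = ""
    color: str = ""
    method: AcquisitionMethod = AcquisitionMethod.ATR

    def __post_init__(self) -> None:
        if not self.sample_name:
            raise ValueError("sample_name must be non-empty")
        if not isinstance(self.method, AcquisitionMethod):
            object.__setattr__(self, "method", AcquisitionMethod(self.method))


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a wavenumber grid."""

    grid: WavenumberGrid
    intensities: np.ndarray
    metadata: SpectrumMetadata = field(
        default_factory=lambda: SpectrumMetadata(sample_name="unnamed")
    )

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1 or y.size != len(self.grid):
            raise ValueError(
                f"intensities length {y.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return len(self.grid)

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass
class ClusterDefinition:
    """A numbered library cluster and the spectrum ids it contains."""

    cluster_number: int
    cluster_name: str
    member_ids: set[str]

    def __post_init__(self) -> None:
        if self.cluster_number <= 0:
            raise ValueError("cluster_number must be a positive integer")
        self.member_ids = set(self.member_ids)
        if not self.member_ids:
            raise ValueError(f"cluster {self.cluster_number} has no members")


@dataclass
class ReferenceLibrary:
    """Cluster-numbered reference spectra on a common wavenumber grid."""

    grid: WavenumberGrid
    entries: dict[str, Spectrum]
    clusters: list[ClusterDefinition]
    spectral_range: tuple[float, float] = (1250.0, 3600.0)
    unassigned: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.spectral_range = (
            min(self.spectral_range),
            max(self.spectral_range),
        )
        self.validate()

    def validate(self) -> None:
        lo, hi = self.grid.extent
        if self.spectral_range[0] < lo - GRID_TOLERANCE or self.spectral_range[1] > hi + GRID_TOLERANCE:
            raise ValueError("spectral_range exceeds grid extent")
        for sid, spec in self.entries.items():
            if not spec.grid.isclose(self.grid):
                raise ValueError(f"entry {sid!r} is not on the library grid")
        numbers = [c.cluster_number for c in self.clusters]
        if len(numbers) != len(set(numbers)):
            raise ValueError("duplicate cluster numbers in library")
        seen: dict[str, int] = {}
        for c in self.clusters:
            for sid in c.member_ids:
                if sid not in self.entries:
                    raise ValueError(
                        f"cluster {c.cluster_number} references unknown spectrum {sid!r}"
                    )
                if sid in seen:
                    raise ValueError(
                        f"spectrum {sid!r} assigned to clusters "
                        f"{seen[sid]} and {c.cluster_number}"
                    )
                seen[sid] = c.cluster_number
        pool = set(self.entries) - set(seen)
        if pool - self.unassigned:
            warnings.warn(
                f"{len(pool - self.unassigned)} spectra belong to no cluster; "
                "placed in the unassigned pool",
                stacklevel=2,
            )
        self.unassigned = pool

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, spectrum_id: str) -> int | None:
        for c in self.clusters:
            if spectrum_id in c.member_ids:
                return c.cluster_number
        return None

    def cluster_by_number(self, number: int) -> ClusterDefinition:
        for c in self.clusters:
            if c.cluster_number == number:
                return c
        raise KeyError(f"no cluster numbered {number}")

    def cluster_name(self, number: int) -> str:
        return self.cluster_by_number(number).cluster_name

    def sorted_ids(self) -> list[str]:
        return sorted(self.entries)


def resample_to_grid(spectrum: Spectrum, target: WavenumberGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Refuses to extrapolate: the target extent must lie inside the source
    extent (no silent padding at the ends of the recorded range).
    """
    if spectrum.grid.isclose(target):
        return replace(spectrum, grid=target)
    src_lo, src_hi = spectrum.grid.extent
    tgt_lo, tgt_hi = target.extent
    if tgt_lo < src_lo - GRID_TOLERANCE or tgt_hi > src_hi + GRID_TOLERANCE:
        raise ValueError(
            f"target grid [{tgt_lo}, {tgt_hi}] requires extrapolation beyond "
            f"source [{src_lo}, {src_hi}]"
        )
    y = np.interp(target.ascending, spectrum.grid.ascending,
                  spectrum.intensities[::-1])[::-1]
    return Spectrum(grid=target, intensities=y, metadata=spectrum.metadata)


def crop_range(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep datapoints with lo <= wavenumber <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError("crop requires lo < hi")
    keep = (spectrum.grid.values >= lo) & (spectrum.grid.values <= hi)
    if keep.sum() < 2:
        raise ValueError(
            f"crop to [{lo}, {hi}] leaves fewer than 2 datapoints"
        )
    return Spectrum(
        grid=WavenumberGrid(spectrum.grid.values[keep]),
        intensities=spectrum.intensities[keep],
        metadata=spectrum.metadata,
    )


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate measurements on identical grids.

    Metadata is carried over from the first replicate (the replicates are the
    same physical sample).
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 replicates to average")
    first = spectra[0]
    for s in spectra[1:]:
        if not s.grid.isclose(first.grid):
            raise ValueError("replicates are not on identical grids")
    y = np.mean([s.intensities for s in spectra], axis=0)
    return first.with_intensities(y)
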