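"""Particle image analysis on pixel assignment maps.

Assigned pixels are split into per-cluster binary masks, gaps are closed
morphologically (a particle whose interior pixels just missed the hit
threshold should still count once, not as a ring of fragments), connected
components become particles, and each particle gets a physical size: the
maximum extent between its pixel centers plus one pixel pitch, so a single
pixel reports exactly the pitch — the minimum detectable particle size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as _sk_label

from .matching import UNASSIGNED, PixelAssignmentMap

__all__ = [
    "Particle",
    "SizeHistogram",
    "default_size_edges",
    "cluster_masks",
    "morphological_close",
    "label_particles",
    "measure_particle",
    "find_particles",
    "particle_table",
    "size_histogram",
    "composition_summary",
    "default_colormap",
    "false_color_image",
]


@dataclass(frozen=True)
class Particle:
    label: int
    cluster_number: int
    pixel_count: int
    size_um: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # r0, c0, r1, c1 (half-open)

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("a particle has at least one pixel")


def cluster_masks(assignment: PixelAssignmentMap) -> dict[int, np.ndarray]:
    """Binary mask per cluster; the masks partition the assigned pixels."""
    out: dict[int, np.ndarray] = {}
    for cnum in np.unique(assignment.cluster):
        if cnum == UNASSIGNED:
            continue
        out[int(cnum)] = assignment.cluster == cnum
    return out


def morphological_close(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Binary closing with a square structuring element of side 2*radius+1.

    Computed on a zero-padded canvas so the result is the true closing over
    an infinite background: extensive (never removes pixels) and idempotent.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return mask.copy()
    mask = np.asarray(mask, dtype=bool)
    pad = 2 * radius
    padded = np.pad(mask, pad)
    st = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    closed = ndimage.binary_erosion(ndimage.binary_dilation(padded, st), st)
    return closed[pad:-pad, pad:-pad]


def label_particles(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labels of a binary mask (8-connected default)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    return _sk_label(np.asarray(mask, dtype=bool), connectivity=1 if connectivity == 4 else 2)


def _max_extent(coords: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance between pixel centers."""
    if len(coords) == 1:
        return 0.0
    pts = coords.astype(float)
    if len(pts) > 400:
        # Feret extent is realized on the convex hull
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) component: brute force below
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def measure_particle(
    coords: np.ndarray | Sequence[tuple[int, int]],
    pixel_pitch: float,
    label: int = 1,
    cluster_number: int = 0,
) -> Particle:
    """Measure one connected component given its pixel coordinates.

    size_um = (max distance between pixel centers) * pitch + pitch, so a
    single pixel reports one pitch (11 um at the default imaging binning).
    """
    coords = np.asarray(list(coords) if not isinstance(coords, np.ndarray) else coords)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("coords must be a non-empty (n, 2) array")
    size_um = _max_extent(coords) * pixel_pitch + pixel_pitch
    centroid = tuple(coords.mean(axis=0))
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0) + 1
    return Particle(
        label=label,
        cluster_number=cluster_number,
        pixel_count=len(coords),
        size_um=float(size_um),
        centroid=(float(centroid[0]), float(centroid[1])),
        bbox=(int(r0), int(c0), int(r1), int(c1)),
    )


def find_particles(
    assignment: PixelAssignmentMap,
    closing_radius: int = 1,
    connectivity: int = 8,
) -> list[Particle]:
    """Full particle extraction: per-cluster close -> label -> measure.

    Closing is applied per cluster mask before labeling; pixels gained by
    closing adopt that mask's cluster. Labels are globally unique, assigned
    in cluster-number order.
    """
    particles: list[Particle] = []
    next_label = 1
    for cnum in sorted(cluster_masks(assignment)):
        closed = morphological_close(assignment.cluster == cnum, closing_radius)
        labels = label_particles(closed, connectivity)
        for comp in range(1, labels.max() + 1):
            coords = np.argwhere(labels == comp)
            particles.append(
                measure_particle(
                    coords, assignment.pixel_pitch, label=next_label, cluster_number=cnum
                )
            )
            next_label += 1
    return particles


def particle_table(
    particles: Sequence[Particle],
    cluster_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Particles as a tidy table (TSV-ready)."""
    rows = [
        {
            "label": p.label,
            "cluster_number": p.cluster_number,
            "cluster_name": (cluster_names or {}).get(p.cluster_number, ""),
            "pixel_count": p.pixel_count,
            "size_um": p.size_um,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "bbox_r0": p.bbox[0],
            "bbox_c0": p.bbox[1],
            "bbox_r1": p.bbox[2],
            "bbox_c1": p.bbox[3],
        }
        for p in particles
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label", "cluster_number", "cluster_name", "pixel_count", "size_um",
            "centroid_row", "centroid_col", "bbox_r0", "bbox_c0", "bbox_r1", "bbox_c1",
        ],
    )


def default_size_edges(pixel_pitch: float = 11.0) -> np.ndarray:
    """Default size-class edges: the pitch, then 20..500 um in 10-um steps."""
    return np.concatenate([[pixel_pitch], np.arange(20.0, 500.0 + 1e-9, 10.0)])


@dataclass(frozen=True)
class SizeHistogram:
    """Per-cluster particle counts over [edge_i, edge_{i+1}) size classes.

    The last class is open-ended. ``counts`` is a DataFrame indexed by the
    lower class edge with one column per cluster.
    """

    class_edges: np.ndarray
    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def fraction_below(self, size_um: float) -> float:
        """Fraction of particles in classes entirely below ``size_um``."""
        if self.total == 0:
            return float("nan")
        edges = self.class_edges
        uppers = np.append(edges[1:], np.inf)
        below = self.counts.loc[uppers <= size_um].to_numpy().sum()
        return float(below / self.total)

    def class_share(self, lower_edge: float) -> float:
        """Fraction of all particles falling in the class at ``lower_edge``."""
        if self.total == 0:
            return float("nan")
        row = self.counts.loc[self.counts.index == lower_edge]
        return float(row.to_numpy().sum() / self.total)


def size_histogram(
    particles: Sequence[Particle], class_edges: np.ndarray | None = None
) -> SizeHistogram:
    """Bin particles into size classes, per cluster."""
    if class_edges is None:
        class_edges = default_size_edges()
    edges = np.asarray(class_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("class edges must increase")
    clusters = sorted({p.cluster_number for p in particles})
    counts = pd.DataFrame(0, index=edges, columns=clusters, dtype=int)
    counts.index.name = "size_class_lower_um"
    for p in particles:
        if p.size_um < edges[0] - 1e-9:
            raise ValueError(
                f"particle size {p.size_um} below the smallest class edge {edges[0]}"
            )
        k = int(np.searchsorted(edges, p.size_um + 1e-9, side="right") - 1)
        counts.iloc[k, counts.columns.get_loc(p.cluster_number)] += 1
    return SizeHistogram(class_edges=edges, counts=counts)


def composition_summary(
    particles: Sequence[Particle],
    plastic_clusters: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-cluster particle counts and percentages.

    Percentages are over all particles; if ``plastic_clusters`` is given, an
    extra column gives the share within that subset only.
    """
    if not particles:
        return pd.DataFrame(
            columns=["cluster_number", "n_particles", "percent", "percent_of_plastic"]
        )
    counts: dict[int, int] = {}
    for p in particles:
        counts[p.cluster_number] = counts.get(p.cluster_number, 0) + 1
    total = sum(counts.values())
    plastic = set(plastic_clusters) if plastic_clusters is not None else None
    plastic_total = (
        sum(v for k, v in counts.items() if k in plastic) if plastic else 0
    )
    rows = []
    for cnum in sorted(counts):
        row = {
            "cluster_number": cnum,
            "n_particles": counts[cnum],
            "percent": 100.0 * counts[cnum] / total,
        }
        if plastic is not None:
            row["percent_of_plastic"] = (
                100.0 * counts[cnum] / plastic_total
                if cnum in plastic and plastic_total
                else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def default_colormap(cluster_numbers: Iterable[int]) -> dict[int, tuple[int, int, int]]:
    """Distinct RGB triples per cluster (UNASSIGNED maps to black)."""
    import matplotlib

    numbers = sorted(set(int(c) for c in cluster_numbers) - {UNASSIGNED})
    cmap = matplotlib.colormaps["tab20"]
    out: dict[int, tuple[int, int, int]] = {UNASSIGNED: (0, 0, 0)}
    for i, cnum in enumerate(numbers):
        r, g, b, _ = cmap(i % 20)
        rgb = (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))
        while rgb in out.values():  # force distinctness past the palette period
            rgb = ((rgb[0] + 37) % 256, (rgb[1] + 91) % 256, (rgb[2] + 53) % 256)
        out[cnum] = rgb
    return out


def false_color_image(
    assignment: PixelAssignmentMap,
    colormap: Mapping[int, tuple[int, int, int]] | None = None,
    path: str | Path | None = None,
) -> np.ndarray:
    """Polymer-type-dependent false-color RGB raster of an assignment map."""
    cmap = dict(colormap) if colormap is not None else default_colormap(
        np.unique(assignment.cluster)
    )
    cmap.setdefault(UNASSIGNED, (0, 0, 0))
    img = np.zeros((*assignment.shape, 3), dtype=np.uint8)
    for cnum, rgb in cmap.items():
        img[assignment.cluster == cnum] = rgb
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(Path(path), img)
    return img
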