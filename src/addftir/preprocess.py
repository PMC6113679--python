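"""Spectrum transformations for database construction and library search.

The database chain mirrors how curated ATR/transmission reference spectra
are prepared before cluster analysis: concave-rubberband baseline
correction, replacement of uninformative regions (ATR crystal artifact,
atmospheric CO2 band) with a straight line, cropping to the imaging range,
clipping of negative absorbances, and closure to percent of total. The
search variants add Savitzky-Golay first derivatives and vector
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import AcquisitionMethod, Spectrum, crop_range

__all__ = [
    "PreprocessConfig",
    "rubberband_baseline",
    "replace_region_with_line",
    "clip_negatives",
    "percent_normalize",
    "vector_normalize",
    "first_derivative",
    "estimate_snr",
    "database_preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the preprocessing chain.

    Defaults follow the curated-database protocol: 10 rubberband iterations
    on 64 baseline points; ATR crystal artifact replaced over 2475-1970
    cm^-1; CO2 band replaced over 2420-2200 cm^-1 for transmission data;
    9-point quadratic Savitzky-Golay derivative; spectra kept only above a
    signal-to-noise ratio of 10.
    """

    rubberband_iterations: int = 10
    rubberband_points: int = 64
    atr_artifact_range: tuple[float, float] = (1970.0, 2475.0)
    co2_range: tuple[float, float] = (2200.0, 2420.0)
    derivative_window: int = 9
    derivative_polyorder: int = 2
    snr_min: float = 10.0
    spectral_range: tuple[float, float] = (1250.0, 3600.0)

    def __post_init__(self) -> None:
        if self.rubberband_iterations < 1:
            raise ValueError("rubberband_iterations must be >= 1")
        if self.rubberband_points < 3:
            raise ValueError("rubberband_points must be >= 3")
        if self.derivative_window % 2 == 0 or self.derivative_window <= self.derivative_polyorder:
            raise ValueError("derivative_window must be odd and > polyorder")
        for name in ("atr_artifact_range", "co2_range", "spectral_range"):
            lo, hi = getattr(self, name)
            object.__setattr__(self, name, (min(lo, hi), max(lo, hi)))


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Monotone-chain lower convex hull of points sorted by ascending x."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # drop i2 if it lies on or above the chord i1->i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (x[i] - x[i1]) * (y[i2] - y[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def lower_convex_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Baseline from the lower convex hull of all (x, y) points (x ascending)."""
    idx = _lower_hull_indices(x, y)
    return np.interp(x, x[idx], y[idx])


def rubberband_baseline(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Concave-rubberband baseline correction.

    The rubber band is the lower convex hull over a set of anchor points
    (``rubberband_points`` evenly spaced, endpoints always included),
    re-stretched under the residual for ``rubberband_iterations`` passes so
    the accumulated baseline hugs concave-up curvature. The estimated
    baseline is subtracted. With anchors at every datapoint and a single
    iteration this reduces exactly to lower-convex-hull subtraction.
    """
    cfg = cfg or PreprocessConfig()
    n = len(spectrum)
    if n < cfg.rubberband_points:
        raise ValueError(
            f"spectrum has {n} points, fewer than rubberband_points={cfg.rubberband_points}"
        )
    x = spectrum.grid.ascending
    y = spectrum.intensities[::-1]
    anchors = np.unique(np.round(np.linspace(0, n - 1, cfg.rubberband_points)).astype(int))
    baseline = np.zeros(n)
    for _ in range(cfg.rubberband_iterations):
        resid = y - baseline
        idx = _lower_hull_indices(x[anchors], resid[anchors])
        baseline = baseline + np.interp(x, x[anchors][idx], resid[anchors][idx])
        # the band may never sit above the data at its anchor points
        baseline[anchors] = np.minimum(baseline[anchors], y[anchors])
    return spectrum.with_intensities((y - baseline)[::-1])


def replace_region_with_line(
    spectrum: Spectrum, region: tuple[float, float]
) -> Spectrum:
    """Replace datapoints inside ``region`` (closed, cm^-1) with a straight line.

    The line joins the nearest datapoints just outside each edge of the
    region, so re-application is a no-op. Regions touching the grid boundary
    are rejected (no anchor on one side).
    """
    lo, hi = min(region), max(region)
    wn = spectrum.grid.values  # descending
    inside = (wn >= lo) & (wn <= hi)
    if not inside.any():
        return spectrum
    idx = np.nonzero(inside)[0]
    first, last = idx[0], idx[-1]  # first = high-wavenumber side
    if first == 0 or last == len(wn) - 1:
        raise ValueError(
            f"region [{lo}, {hi}] touches the grid boundary; no outside anchor"
        )
    x0, y0 = wn[first - 1], spectrum.intensities[first - 1]
    x1, y1 = wn[last + 1], spectrum.intensities[last + 1]
    y = spectrum.intensities.copy()
    y[inside] = y0 + (y1 - y0) * (wn[inside] - x0) / (x1 - x0)
    return spectrum.with_intensities(y)


def clip_negatives(spectrum: Spectrum) -> Spectrum:
    """Set all negative absorbances to zero."""
    return spectrum.with_intensities(np.maximum(spectrum.intensities, 0.0))


def percent_normalize(spectrum: Spectrum) -> Spectrum:
    """Closure to percent of total: each value x 100 / sum. Requires sum > 0."""
    y = spectrum.intensities
    if np.any(y < 0):
        raise ValueError("percent_normalize requires non-negative intensities")
    total = y.sum()
    if total <= 0:
        raise ValueError("cannot percent-normalize an all-zero spectrum")
    return spectrum.with_intensities(y * (100.0 / total))


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm."""
    norm = np.linalg.norm(spectrum.intensities)
    if norm == 0:
        raise ValueError("cannot vector-normalize a zero spectrum")
    return spectrum.with_intensities(spectrum.intensities / norm)


def first_derivative(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky-Golay smoothed first derivative d(absorbance)/d(wavenumber).

    Output stays on the input grid; edge points come from one-sided
    polynomial fits (``mode='interp'``). The grid must be uniformly spaced.
    """
    cfg = cfg or PreprocessConfig()
    if len(spectrum) < cfg.derivative_window:
        raise ValueError("spectrum shorter than the derivative window")
    delta = spectrum.grid.spacing()
    # differentiate on the ascending axis, then flip back to descending
    dy = savgol_filter(
        spectrum.intensities[::-1],
        window_length=cfg.derivative_window,
        polyorder=cfg.derivative_polyorder,
        deriv=1,
        delta=delta,
        mode="interp",
    )
    return spectrum.with_intensities(dy[::-1])


def estimate_snr(
    spectrum: Spectrum,
    signal_range: tuple[float, float],
    noise_range: tuple[float, float],
) -> float:
    """Signal-to-noise ratio for low-quality exclusion.

    SNR = (max in signal window - median in signal window) / standard
    deviation of the linearly detrended noise window. A zero-variance noise
    window yields +inf (nothing to measure noise against).
    """
    wn = spectrum.grid.values
    sig_mask = (wn >= min(signal_range)) & (wn <= max(signal_range))
    noi_mask = (wn >= min(noise_range)) & (wn <= max(noise_range))
    if sig_mask.sum() < 2 or noi_mask.sum() < 3:
        raise ValueError("signal/noise ranges must each cover the grid")
    sig = spectrum.intensities[sig_mask]
    noi = spectrum.intensities[noi_mask]
    xn = wn[noi_mask]
    coef = np.polyfit(xn, noi, 1)
    sigma = float(np.std(noi - np.polyval(coef, xn), ddof=1))
    if sigma == 0:
        return float("inf")
    return float((sig.max() - np.median(sig)) / sigma)


def database_preprocess(
    spectrum: Spectrum, cfg: PreprocessConfig | None = None
) -> Spectrum:
    """Full database chain, in the fixed canonical order.

    rubberband baseline -> straight-line replacement of the ATR crystal
    artifact (ATR spectra) or the CO2 band (transmission spectra) -> crop to
    the imaging spectral range -> clip negatives -> percent-normalize.
    The chain is invariant to positive scaling of the input.
    """
    cfg = cfg or PreprocessConfig()
    s = rubberband_baseline(spectrum, cfg)
    if spectrum.metadata.method is AcquisitionMethod.ATR:
        s = replace_region_with_line(s, cfg.atr_artifact_range)
    else:
        s = replace_region_with_line(s, cfg.co2_range)
    s = crop_range(s, *cfg.spectral_range)
    s = clip_negatives(s)
    return percent_normalize(s)
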