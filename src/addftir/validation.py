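"""Expert-style quality scoring and comparison of analysis runs.

The five-level quality score mirrors manual spectral validation practice:
an analyst compares an identified spectrum to its assigned reference and
counts minor and major band differences. The score is a pure lookup on
those counts — the judgment of what constitutes a minor or major difference
stays with the analyst and is *not* automated here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import UNASSIGNED

__all__ = [
    "QUALITY_LEVELS",
    "score_spectrum",
    "ValidationRecord",
    "ConfusionSummary",
    "validate_against_truth",
    "compare_runs",
]

QUALITY_LEVELS = (1.0, 0.75, 0.5, 0.25, 0.01)


def score_spectrum(n_minor: int, n_major: int) -> float:
    """Quality score from counts of minor/major differences to the reference.

    1 = no difference; 0.75 = one minor; 0.5 = two minor; 0.25 = three minor
    or one major; 0.01 = more than three minor, more than one major, or any
    mix of minor and major differences.
    """
    if n_minor < 0 or n_major < 0:
        raise ValueError("difference counts must be non-negative")
    if n_major == 0:
        if n_minor == 0:
            return 1.0
        if n_minor == 1:
            return 0.75
        if n_minor == 2:
            return 0.5
        if n_minor == 3:
            return 0.25
        return 0.01
    if n_major == 1 and n_minor == 0:
        return 0.25
    return 0.01


@dataclass(frozen=True)
class ValidationRecord:
    """One manually validated assignment."""

    item_id: str
    assigned_cluster: int
    expected_cluster: int
    n_minor: int
    n_major: int

    @property
    def score(self) -> float:
        return score_spectrum(self.n_minor, self.n_major)


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-cluster and overall agreement with ground truth."""

    per_cluster: pd.DataFrame  # index expected cluster: correct/misassigned/unassigned
    n_total: int

    @property
    def percent_correct(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.per_cluster["correct"].sum() / self.n_total

    @property
    def percent_misassigned(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.per_cluster["misassigned"].sum() / self.n_total

    @property
    def percent_unassigned(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.per_cluster["unassigned"].sum() / self.n_total


def validate_against_truth(
    assigned: Sequence[int] | np.ndarray,
    truth: Sequence[int] | np.ndarray,
) -> ConfusionSummary:
    """Compare assigned cluster numbers to ground truth, item by item.

    Items may be pixels or particles; 0 marks an unassigned item. Only items
    with a truth label (truth != 0) enter the summary.
    """
    a = np.asarray(assigned).ravel()
    t = np.asarray(truth).ravel()
    if a.shape != t.shape:
        raise ValueError("assigned and truth must have the same length")
    keep = t != UNASSIGNED
    a, t = a[keep], t[keep]
    rows = []
    for cnum in np.unique(t):
        at = a[t == cnum]
        rows.append(
            {
                "expected_cluster": int(cnum),
                "correct": int(np.sum(at == cnum)),
                "misassigned": int(np.sum((at != cnum) & (at != UNASSIGNED))),
                "unassigned": int(np.sum(at == UNASSIGNED)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["expected_cluster", "correct", "misassigned", "unassigned"]
    ).set_index("expected_cluster")
    return ConfusionSummary(per_cluster=df, n_total=int(len(t)))


def compare_runs(
    particles_a: pd.DataFrame,
    particles_b: pd.DataFrame,
    assignment_a: np.ndarray | None = None,
    assignment_b: np.ndarray | None = None,
) -> dict:
    """Compare two analysis runs of the same sample.

    Returns per-cluster particle-count deltas (a minus b) and, when both
    pixel maps are supplied, the fraction of pixels on which they agree.
    """
    def counts(df: pd.DataFrame) -> Mapping[int, int]:
        if df.empty:
            return {}
        return df.groupby("cluster_number").size().to_dict()

    ca, cb = counts(particles_a), counts(particles_b)
    deltas = {
        int(k): int(ca.get(k, 0) - cb.get(k, 0)) for k in sorted(set(ca) | set(cb))
    }
    out: dict = {
        "particle_count_delta": deltas,
        "n_particles_a": int(sum(ca.values())),
        "n_particles_b": int(sum(cb.values())),
    }
    if assignment_a is not None and assignment_b is not None:
        a = np.asarray(assignment_a)
        b = np.asarray(assignment_b)
        if a.shape != b.shape:
            raise ValueError("assignment maps differ in shape")
        out["pixel_agreement"] = float(np.mean(a == b))
    return out
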