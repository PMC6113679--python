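"""Hellinger-distance hierarchical clustering, the SIMPROF stopping rule,
and the curation operations that turn a dendrogram into numbered library
clusters.

Percent-normalized spectra are compositional, so resemblance between them is
measured with the Hellinger distance

    D(p, q) = sqrt( sum_i ( sqrt(p_i/P) - sqrt(q_i/Q) )^2 ),   P = sum p, Q = sum q,

which ranges from 0 (identical band profiles) to sqrt(2) (disjoint support).
Agglomeration uses group-average linkage (UPGMA) by default. SIMPROF is a
permutation test for multivariate structure inside a candidate group: the
observed ordered resemblance profile is compared against its expectation
under independent within-variable permutations, and the departure statistic
pi is referred to a permutation null. SIMPROF output is advisory — final
cluster tables are authored through the curation ledger, which records every
merge/split/add so the published table is exactly replayable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage, to_tree

from .spectra import ClusterDefinition, ReferenceLibrary, Spectrum

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "SimprofResult",
    "CurationOp",
    "CurationLedger",
    "hellinger_distance",
    "pairwise_distances",
    "hierarchical_cluster",
    "simprof_test",
    "simprof_partition",
    "merge_clusters",
    "split_cluster",
    "add_material",
    "remove_cluster",
    "renumber_cluster",
]

MAX_HELLINGER = float(np.sqrt(2.0))


def _as_values(x: Spectrum | np.ndarray) -> np.ndarray:
    return x.intensities if isinstance(x, Spectrum) else np.asarray(x, dtype=float)


def hellinger_distance(p: Spectrum | np.ndarray, q: Spectrum | np.ndarray) -> float:
    """Hellinger distance between two non-negative spectra (range [0, sqrt 2])."""
    pv, qv = _as_values(p), _as_values(q)
    if isinstance(p, Spectrum) and isinstance(q, Spectrum) and not p.grid.isclose(q.grid):
        raise ValueError("spectra are not on the same grid")
    if pv.shape != qv.shape:
        raise ValueError("length mismatch")
    if np.any(pv < 0) or np.any(qv < 0):
        raise ValueError("negative intensities; clip_negatives must precede")
    sp, sq = pv.sum(), qv.sum()
    if sp <= 0 or sq <= 0:
        raise ValueError("each spectrum must have a positive total")
    return float(np.sqrt(np.sum((np.sqrt(pv / sp) - np.sqrt(qv / sq)) ** 2)))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with stable id order."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]


def _hellinger_sqrt_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("negative values in data matrix")
    totals = X.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every row must have a positive total")
    return np.sqrt(X / totals)


def hellinger_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs Hellinger distances between the rows of ``X``."""
    R = _hellinger_sqrt_rows(X)
    S = R @ R.T
    return np.sqrt(np.clip(2.0 - 2.0 * S, 0.0, None))


def pairwise_distances(
    spectra: Sequence[Spectrum] | np.ndarray, ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Hellinger :class:`DistanceMatrix` over a sequence of spectra or rows."""
    if isinstance(spectra, np.ndarray):
        X = spectra
        the_ids = list(ids) if ids is not None else [str(i) for i in range(len(X))]
    else:
        X = np.stack([s.intensities for s in spectra])
        the_ids = (
            list(ids)
            if ids is not None
            else [s.metadata.sample_name for s in spectra]
        )
        if len(set(the_ids)) != len(the_ids):
            the_ids = [f"{i}:{t}" for i, t in enumerate(the_ids)]
    D = hellinger_matrix(X)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(ids=tuple(the_ids), values=D)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in scipy linkage encoding.

    ``merges[k] = (left, right, height, size)`` with leaves 0..n-1 ordered as
    ``leaf_ids``; internal node k has id n+k.
    """

    merges: np.ndarray
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        Z = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if Z.shape != (n - 1, 4):
            raise ValueError("need n-1 merges for n leaves")
        object.__setattr__(self, "merges", Z)
        object.__setattr__(self, "leaf_ids", tuple(self.leaf_ids))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root = to_tree(self.merges)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id].replace(" ", "_")
            parts = ",".join(
                f"{rec(ch)}:{max(node.dist - ch.dist, 0.0):.6g}"
                for ch in (node.left, node.right)
            )
            return f"({parts})"

        return rec(root) + ";"

    def node_leafsets(self) -> dict[int, list[int]]:
        """Leaf indices under every node id (leaves and internal)."""
        n = self.n_leaves
        sets: dict[int, list[int]] = {i: [i] for i in range(n)}
        for k, (a, b, _, _) in enumerate(self.merges[:, :4]):
            sets[n + k] = sets[int(a)] + sets[int(b)]
        return sets


def hierarchical_cluster(
    dist: DistanceMatrix, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix (UPGMA by default)."""
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if dist.n < 2:
        raise ValueError("need at least 2 items to cluster")
    cond = dist.condensed()
    if np.any(~np.isfinite(cond)):
        raise ValueError("distance matrix contains NaN/inf")
    Z = _scipy_linkage(cond, method=linkage)
    return Dendrogram(merges=Z, leaf_ids=dist.ids)


# --------------------------------------------------------------------------
# SIMPROF


@dataclass(frozen=True)
class SimprofResult:
    """Outcome of a similarity-profile permutation test on one group."""

    node: int | None
    pi_statistic: float
    p_value: float
    alpha: float
    homogeneous: bool
    n_members: int = 0
    tested: bool = True


def _sorted_profiles(X3: np.ndarray) -> np.ndarray:
    """Sorted upper-triangle Hellinger profiles for a (B, n, p) batch."""
    R = _hellinger_sqrt_rows(X3)
    S = np.einsum("bip,bjp->bij", R, R)
    iu = np.triu_indices(X3.shape[1], 1)
    d = np.sqrt(np.clip(2.0 - 2.0 * S[:, iu[0], iu[1]], 0.0, None))
    return np.sort(d, axis=1)


def _permuted_profiles(
    X: np.ndarray, n_perm: int, rng: np.random.Generator, batch: int = 512
) -> np.ndarray:
    """Profiles of ``n_perm`` datasets with each variable independently permuted."""
    n, p = X.shape
    out = []
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.argsort(rng.random((b, n, p)), axis=1)
        Xp = np.take_along_axis(np.broadcast_to(X, (b, n, p)), idx, axis=1)
        out.append(_sorted_profiles(Xp))
        done += b
    return np.concatenate(out, axis=0)


def simprof_test(
    data: np.ndarray,
    alpha: float = 0.05,
    n_perm_mean: int = 999,
    n_perm_null: int = 999,
    seed: int = 0,
    node: int | None = None,
) -> SimprofResult:
    """Similarity-profile test for internal structure of one group.

    ``data`` holds one row per group member (non-negative spectra; rows are
    rescaled to relative abundances internally). The observed ordered
    Hellinger resemblances are compared to their mean profile under
    ``n_perm_mean`` within-variable permutations; the departure
    ``pi = sum_k |d_(k) - mean_(k)|`` is referred to ``n_perm_null`` further
    permutations. Groups of fewer than three members carry no testable
    profile and are declared homogeneous.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D samples x variables matrix")
    n = X.shape[0]
    if n <= 2:
        # a single resemblance (or none) has no profile to test
        return SimprofResult(node, 0.0, 1.0, alpha, True, n_members=n, tested=False)
    rng = np.random.default_rng(seed)
    obs = _sorted_profiles(X[None])[0]
    mean_profile = _permuted_profiles(X, n_perm_mean, rng).mean(axis=0)
    pi_obs = float(np.abs(obs - mean_profile).sum())
    null = _permuted_profiles(X, n_perm_null, rng)
    pi_null = np.abs(null - mean_profile).sum(axis=1)
    p = float((1 + np.sum(pi_null >= pi_obs)) / (1 + n_perm_null))
    return SimprofResult(
        node, pi_obs, p, alpha, homogeneous=p >= alpha, n_members=n, tested=True
    )


def simprof_partition(
    dendrogram: Dendrogram,
    data: np.ndarray,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm_mean: int = 999,
    n_perm_null: int = 999,
) -> list[SimprofResult | list[int]]:
    """Descend the dendrogram, testing each node; return the homogeneous groups.

    The traversal starts at the root: a node whose profile shows no
    significant structure stops the descent (its leaves form one group);
    otherwise both children are visited. Returns the groups as lists of leaf
    indices into ``dendrogram.leaf_ids``, in left-to-right tree order. This
    output is advisory — cluster tables are authored via the curation ledger.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[0] != dendrogram.n_leaves:
        raise ValueError("data rows must match dendrogram leaves")
    root = to_tree(dendrogram.merges)
    groups: list[list[int]] = []

    def visit(node) -> None:
        leaves = node.pre_order(lambda v: v.id)
        if len(leaves) <= 2:
            groups.append(sorted(leaves))
            return
        res = simprof_test(
            X[sorted(leaves)],
            alpha=alpha,
            n_perm_mean=n_perm_mean,
            n_perm_null=n_perm_null,
            seed=np.random.default_rng([seed, node.id]).integers(2**31),
            node=node.id,
        )
        if res.homogeneous:
            groups.append(sorted(leaves))
        else:
            visit(node.left)
            visit(node.right)

    visit(root)
    return groups


# --------------------------------------------------------------------------
# Curation operations and ledger


@dataclass
class CurationOp:
    """One recorded curation step (merge / split / add / remove / renumber)."""

    kind: str
    params: dict
    note: str = ""

    def to_line(self) -> str:
        import json

        payload = {
            k: (sorted(v) if isinstance(v, set) else v)
            for k, v in self.params.items()
            if k != "spectra"
        }
        if "spectra" in self.params:
            payload["spectrum_ids"] = sorted(self.params["spectra"])
        return f"{self.kind}\t{json.dumps(payload, sort_keys=True)}\t{self.note}"


@dataclass
class CurationLedger:
    """Ordered record of curation operations; replaying it is exact."""

    ops: list[CurationOp] = field(default_factory=list)

    def append(self, op: CurationOp) -> None:
        self.ops.append(op)

    def to_text(self) -> str:
        return "\n".join(op.to_line() for op in self.ops) + ("\n" if self.ops else "")

    def replay(self, library: ReferenceLibrary) -> ReferenceLibrary:
        """Apply every recorded operation to ``library`` in order."""
        lib = library
        for op in self.ops:
            if op.kind == "merge":
                lib = merge_clusters(lib, set(op.params["numbers"]))
            elif op.kind == "split":
                lib = split_cluster(lib, op.params["number"], op.params["partition"])
            elif op.kind == "add":
                lib, _ = add_material(
                    lib,
                    op.params["spectra"],
                    op.params["mode"],
                    cluster_name=op.params.get("cluster_name"),
                )
            elif op.kind == "remove":
                lib = remove_cluster(lib, op.params["number"])
            elif op.kind == "renumber":
                lib = renumber_cluster(lib, op.params["old"], op.params["new"])
            else:
                raise ValueError(f"unknown curation op {op.kind!r}")
        return lib


def _copy_library(library: ReferenceLibrary) -> ReferenceLibrary:
    return ReferenceLibrary(
        grid=library.grid,
        entries=dict(library.entries),
        clusters=[
            ClusterDefinition(c.cluster_number, c.cluster_name, set(c.member_ids))
            for c in library.clusters
        ],
        spectral_range=library.spectral_range,
        unassigned=set(library.unassigned),
    )


def merge_clusters(
    library: ReferenceLibrary,
    numbers: Iterable[int],
    ledger: CurationLedger | None = None,
    note: str = "",
) -> ReferenceLibrary:
    """Union the named clusters under the lowest of their numbers."""
    numbers = sorted(set(int(n) for n in numbers))
    lib = _copy_library(library)
    targets = [lib.cluster_by_number(n) for n in numbers]
    if len(targets) > 1:
        keep = targets[0]
        keep.cluster_name = " + ".join(t.cluster_name for t in targets)
        for t in targets[1:]:
            keep.member_ids |= t.member_ids
            lib.clusters.remove(t)
    lib.validate()
    if ledger is not None:
        ledger.append(CurationOp("merge", {"numbers": numbers}, note))
    return lib


def split_cluster(
    library: ReferenceLibrary,
    number: int,
    partition: Mapping[str, str],
    ledger: CurationLedger | None = None,
    note: str = "",
) -> ReferenceLibrary:
    """Reassign a cluster's members to new named clusters.

    ``partition`` maps every member id to its new cluster name. A partition
    with a single target name is a pure rename (the number is kept);
    otherwise the original number is retired and the new clusters take fresh
    numbers after the current maximum, in sorted-name order.
    """
    lib = _copy_library(library)
    src = lib.cluster_by_number(number)
    if set(partition) != src.member_ids:
        raise ValueError("partition must cover exactly the cluster's members")
    names = sorted(set(partition.values()))
    if len(names) == 1:
        src.cluster_name = names[0]
    else:
        lib.clusters.remove(src)
        next_num = max(c.cluster_number for c in library.clusters) + 1
        for name in names:
            members = {sid for sid, nm in partition.items() if nm == name}
            lib.clusters.append(ClusterDefinition(next_num, name, members))
            next_num += 1
    lib.validate()
    if ledger is not None:
        ledger.append(
            CurationOp("split", {"number": number, "partition": dict(partition)}, note)
        )
    return lib


def add_material(
    library: ReferenceLibrary,
    spectra: Mapping[str, Spectrum],
    mode: str | int = "new_cluster",
    cluster_name: str | None = None,
    linkage: str = "average",
    ledger: CurationLedger | None = None,
    note: str = "",
) -> tuple[ReferenceLibrary, Dendrogram]:
    """Add new preprocessed spectra and re-run the cluster analysis.

    ``mode='new_cluster'`` bins all added spectra into one fresh numbered
    cluster (``cluster_name`` required); an integer mode adds them to that
    existing cluster. The returned dendrogram spans the extended entry set.
    """
    lib = _copy_library(library)
    for sid, spec in spectra.items():
        if sid in lib.entries:
            raise ValueError(f"spectrum id {sid!r} already in library")
        if not spec.grid.isclose(lib.grid):
            raise ValueError(f"spectrum {sid!r} is not on the library grid")
        lib.entries[sid] = spec
    if mode == "new_cluster":
        if not cluster_name:
            raise ValueError("new_cluster mode needs a cluster_name")
        next_num = max((c.cluster_number for c in lib.clusters), default=0) + 1
        lib.clusters.append(
            ClusterDefinition(next_num, cluster_name, set(spectra))
        )
    else:
        lib.cluster_by_number(int(mode)).member_ids |= set(spectra)
    lib.validate()
    ids = lib.sorted_ids()
    dm = pairwise_distances([lib.entries[i] for i in ids], ids=ids)
    dendro = hierarchical_cluster(dm, linkage=linkage)
    if ledger is not None:
        ledger.append(
            CurationOp(
                "add",
                {"spectra": dict(spectra), "mode": mode, "cluster_name": cluster_name},
                note,
            )
        )
    return lib, dendro


def remove_cluster(
    library: ReferenceLibrary,
    number: int,
    ledger: CurationLedger | None = None,
    note: str = "",
) -> ReferenceLibrary:
    """Drop a cluster; its spectra move to the unassigned pool."""
    lib = _copy_library(library)
    c = lib.cluster_by_number(number)
    lib.clusters.remove(c)
    lib.unassigned |= c.member_ids
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lib.validate()
    if ledger is not None:
        ledger.append(CurationOp("remove", {"number": number}, note))
    return lib


def renumber_cluster(
    library: ReferenceLibrary,
    old: int,
    new: int,
    ledger: CurationLedger | None = None,
    note: str = "",
) -> ReferenceLibrary:
    lib = _copy_library(library)
    if any(c.cluster_number == new for c in lib.clusters):
        raise ValueError(f"cluster number {new} already in use")
    lib.cluster_by_number(old).cluster_number = new
    lib.validate()
    if ledger is not None:
        ledger.append(CurationOp("renumber", {"old": old, "new": new}, note))
    return lib
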