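import numpy as np
import pytest

from addftir import (
    CurationLedger,
    DistanceMatrix,
    add_material,
    hellinger_distance,
    hierarchical_cluster,
    merge_clusters,
    pairwise_distances,
    remove_cluster,
    simprof_partition,
    simprof_test,
    split_cluster,
    synth_library,
)
from addftir.clustering import MAX_HELLINGER, hellinger_matrix
from addftir.synth import BandSpec, default_imaging_grid, synth_spectrum


class TestHellinger:
    def test_identical_spectra_distance_zero(self):
        p = np.array([10.0, 20.0, 70.0])
        assert hellinger_distance(p, 3 * p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_sqrt2(self):
        assert hellinger_distance(
            np.array([100.0, 0.0]), np.array([0.0, 100.0])
        ) == pytest.approx(MAX_HELLINGER)

    def test_closed_form_half_split(self):
        d = hellinger_distance(np.array([50.0, 50.0]), np.array([100.0, 0.0]))
        assert d == pytest.approx(np.sqrt((np.sqrt(0.5) - 1) ** 2 + 0.5), abs=1e-9)
        assert d == pytest.approx(0.76537, abs=1e-5)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="clip_negatives"):
            hellinger_distance(np.array([-1.0, 2.0]), np.array([1.0, 1.0]))

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p, q, r = rng.uniform(0.0, 1.0, (3, 12))
            dpq = hellinger_distance(p, q)
            dqp = hellinger_distance(q, p)
            dpr = hellinger_distance(p, r)
            dqr = hellinger_distance(q, r)
            assert dpq == pytest.approx(dqp, abs=1e-12)
            assert 0.0 <= dpq <= MAX_HELLINGER + 1e-12
            assert dpq <= dpr + dqr + 1e-9  # triangle inequality
        assert hellinger_distance(p, p) == pytest.approx(0.0, abs=1e-12)


class TestPairwise:
    def test_single_item_matrix(self):
        dm = pairwise_distances(np.array([[1.0, 2.0]]))
        assert dm.values.shape == (1, 1) and dm.values[0, 0] == 0.0

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 1.0, (6, 20))
        dm = pairwise_distances(X)
        for i in range(6):
            for j in range(6):
                assert dm.values[i, j] == pytest.approx(
                    hellinger_distance(X[i], X[j]), abs=1e-9
                )


def _naive_upgma(D: np.ndarray):
    """O(n^3) group-average agglomeration; ties broken by smallest (i, j).

    Returns the cophenetic distance matrix, which is label-invariant.
    """
    n = len(D)
    members = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        best = min(
            ((dist[tuple(sorted((a, b)))], a, b)
             for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, a, b = best
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = h
        members[nxt] = members[a] + members[b]
        for c in active:
            if c in (a, b):
                continue
            da = dist[tuple(sorted((a, c)))]
            db = dist[tuple(sorted((b, c)))]
            wa, wb = len(members[a]), len(members[b])
            dist[tuple(sorted((nxt, c)))] = (wa * da + wb * db) / (wa + wb)
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return coph


class TestHierarchical:
    def test_two_leaves_merge_at_their_distance(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.7], [0.7, 0.0]]))
        dendro = hierarchical_cluster(dm)
        assert dendro.merges[0, 2] == pytest.approx(0.7)

    def test_three_point_hand_example(self):
        D = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dendro = hierarchical_cluster(DistanceMatrix(("A", "B", "C"), D))
        heights = sorted(dendro.merges[:, 2])
        assert heights == pytest.approx([1.0, 4.0])

    def test_agreement_with_naive_oracle(self):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        for _ in range(8):
            cond = rng.uniform(0.1, 2.0, 8 * 7 // 2)
            D = squareform(cond)
            dendro = hierarchical_cluster(
                DistanceMatrix(tuple("abcdefgh"), D)
            )
            got = squareform(cophenet(dendro.merges))
            want = _naive_upgma(D)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_heights_monotone_rootward(self, library5):
        ids = library5.sorted_ids()
        dm = pairwise_distances([library5.entries[i] for i in ids], ids=ids)
        dendro = hierarchical_cluster(dm)
        heights = dendro.merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_nan_distance_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            hierarchical_cluster(DistanceMatrix(("a", "b"), D))

    def test_newick_export_contains_all_leaves(self, library5):
        ids = library5.sorted_ids()
        dm = pairwise_distances([library5.entries[i] for i in ids], ids=ids)
        nwk = hierarchical_cluster(dm).to_newick()
        assert nwk.endswith(";")
        for sid in ids:
            assert sid in nwk


def _two_block_data(noise=0.0, per_block=4, seed=0):
    g = default_imaging_grid()
    a = synth_spectrum([BandSpec(2900, 30, 1.0), BandSpec(1500, 25, 0.7)], g).intensities
    b = synth_spectrum([BandSpec(3300, 40, 0.9), BandSpec(1750, 20, 0.8)], g).intensities
    X = np.vstack([a] * per_block + [b] * per_block)
    if noise:
        rng = np.random.default_rng(seed)
        X = np.abs(X + rng.normal(0, noise, X.shape))
    return X


class TestSimprof:
    def test_identical_spectra_are_homogeneous(self):
        X = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (5, 1))
        r = simprof_test(X, seed=0)
        assert r.pi_statistic == 0.0 and r.homogeneous

    def test_pair_is_homogeneous_by_definition(self):
        r = simprof_test(np.random.default_rng(0).uniform(size=(2, 10)), seed=0)
        assert r.homogeneous and not r.tested

    def test_two_block_structure_detected(self):
        r = simprof_test(_two_block_data(noise=0.02, seed=7), alpha=0.05, seed=1)
        assert r.p_value < 0.01 and not r.homogeneous

    def test_deterministic_given_seed(self):
        X = _two_block_data(noise=0.05, seed=3)
        r1 = simprof_test(X, seed=42)
        r2 = simprof_test(X, seed=42)
        assert r1.pi_statistic == r2.pi_statistic and r1.p_value == r2.p_value

    def test_partition_fully_homogeneous_data_single_group(self):
        X = np.tile(np.array([5.0, 1.0, 3.0, 2.0]), (6, 1))
        dm = pairwise_distances(X)
        dendro = hierarchical_cluster(dm)
        groups = simprof_partition(dendro, X, seed=0)
        assert len(groups) == 1 and sorted(groups[0]) == list(range(6))

    def test_partition_recovers_two_blocks(self):
        X = _two_block_data(noise=0.0)
        dendro = hierarchical_cluster(pairwise_distances(X))
        groups = simprof_partition(dendro, X, alpha=0.05, seed=0)
        assert sorted(map(sorted, groups)) == [[0, 1, 2, 3], [4, 5, 6, 7]]


class TestCuration:
    def test_merge_single_cluster_is_identity(self, library5):
        out = merge_clusters(library5, {3})
        assert {c.cluster_number for c in out.clusters} == {1, 2, 3, 4, 5}

    def test_merge_unions_members_under_lowest_number(self, library5):
        out = merge_clusters(library5, {1, 2})
        merged = out.cluster_by_number(1)
        n1 = len(library5.cluster_by_number(1).member_ids)
        n2 = len(library5.cluster_by_number(2).member_ids)
        assert len(merged.member_ids) == n1 + n2
        with pytest.raises(KeyError):
            out.cluster_by_number(2)

    def test_split_all_to_one_name_is_rename(self, library5):
        members = library5.cluster_by_number(2).member_ids
        out = split_cluster(library5, 2, {m: "renamed" for m in members})
        assert out.cluster_by_number(2).cluster_name == "renamed"

    def test_split_conserves_members_with_fresh_numbers(self, imaging_grid):
        lib = synth_library(1, seed=9, grid=imaging_grid)
        lib, _ = add_material(
            lib,
            {f"extra_{i}": lib.entries["polymer_01"] for i in range(2)},
            mode=1,
        )
        members = sorted(lib.cluster_by_number(1).member_ids)
        partition = {m: ("left" if i < 2 else "right") for i, m in enumerate(members)}
        out = split_cluster(lib, 1, partition)
        new = [c for c in out.clusters if c.cluster_name in ("left", "right")]
        assert sum(len(c.member_ids) for c in new) == len(members)
        assert not (new[0].member_ids & new[1].member_ids)

    def test_add_material_as_new_clusters(self, library5):
        coal_like = {f"coal_{i}": library5.entries["polymer_01"] for i in range(4)}
        char_like = {f"char_{i}": library5.entries["polymer_02"] for i in range(2)}
        lib, dendro = add_material(library5, coal_like, "new_cluster", cluster_name="coal")
        lib, dendro = add_material(lib, char_like, "new_cluster", cluster_name="charcoal")
        assert lib.n_clusters == library5.n_clusters + 2
        assert dendro.n_leaves == len(library5.entries) + 6

    def test_add_to_existing_cluster_keeps_count(self, library5):
        lib, dendro = add_material(
            library5, {"extra": library5.entries["polymer_03"]}, mode=3
        )
        assert lib.n_clusters == library5.n_clusters
        assert dendro.n_leaves == len(library5.entries) + 1

    def test_ledger_replay_reproduces_final_state(self, library5):
        ledger = CurationLedger()
        lib = merge_clusters(library5, {1, 2}, ledger=ledger)
        lib = remove_cluster(lib, 5, ledger=ledger)
        lib, _ = add_material(
            lib,
            {"new_1": library5.entries["polymer_04"]},
            "new_cluster",
            cluster_name="added",
            ledger=ledger,
        )
        replayed = ledger.replay(library5)
        a = {c.cluster_number: (c.cluster_name, frozenset(c.member_ids)) for c in lib.clusters}
        b = {c.cluster_number: (c.cluster_name, frozenset(c.member_ids)) for c in replayed.clusters}
        assert a == b
        assert sorted(lib.entries) == sorted(replayed.entries)

    def test_ledger_text_has_one_line_per_op(self, library5):
        ledger = CurationLedger()
        merge_clusters(library5, {1, 2}, ledger=ledger, note="interference")
        remove_cluster(library5, 4, ledger=ledger)
        text = ledger.to_text()
        assert len(text.strip().splitlines()) == 2
        assert text.startswith("merge\t")
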