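"""Dataset filtering, diversity indices, IBS, ordination and trees."""

import numpy as np
import pytest
import skbio
from hypothesis import given, settings
from hypothesis import strategies as st

from mdgkit.marker_catalog import MISSING, GenotypeMatrix
from mdgkit.diversity import (
    LESS_STRICT,
    STRICT,
    DistanceMatrix,
    EmptyFilterResult,
    FilterSpec,
    classical_mds,
    filter_dataset,
    ibs_distance,
    neighbor_joining,
    per_set_summary,
    read_newick,
    read_ordination,
    write_newick,
    write_ordination,
)
from mdgkit.simulate import PopulationSpec, SetSpec, simulate_population


def make_matrix(calls, ploidy=2, labels=None):
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        calls=calls,
        ploidy_scale=np.full(m, ploidy),
        set_labels=labels,
    )


class TestFilterDataset:
    def test_hand_checkable_toy(self):
        # marker calls per column: m0 -> 3, m1 -> 4, m2 -> 2
        calls = [
            [0, 1, MISSING],
            [1, 1, 0],
            [MISSING, 2, MISSING],
            [2, 0, 1],
        ]
        matrix = make_matrix(calls)
        out, ledger = filter_dataset(matrix, FilterSpec(3, 0.75, "toy"))
        # m2 dropped (2 < 3 calls); then s2 has 1/2 = 0.5 < 0.75 present
        assert out.marker_ids == ["m0", "m1"]
        assert out.sample_ids == ["s0", "s1", "s3"]
        assert ledger.n_sites_removed == 1
        assert ledger.n_samples_removed == 1

    def test_zero_thresholds_are_identity(self, toy_matrix):
        out, ledger = filter_dataset(toy_matrix, FilterSpec(0, 0.0, "none"))
        assert out == toy_matrix
        assert ledger.n_sites_removed == 0 and ledger.n_samples_removed == 0

    def test_idempotent(self, toy_matrix):
        spec = FilterSpec(3, 0.5, "once")
        once, _ = filter_dataset(toy_matrix, spec)
        twice, ledger = filter_dataset(once, spec)
        assert twice == once
        assert ledger.n_sites_removed == 0 and ledger.n_samples_removed == 0

    def test_everything_filtered_is_explicit_error(self, toy_matrix):
        with pytest.raises(EmptyFilterResult):
            filter_dataset(toy_matrix, FilterSpec(10**6, 1.0, "impossible"))

    def test_presets_as_published(self):
        assert (STRICT.min_site_calls, STRICT.min_sample_present_fraction) == (2000, 0.95)
        assert (LESS_STRICT.min_site_calls,
                LESS_STRICT.min_sample_present_fraction) == (2700, 0.90)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_brute_force_recheck(self, seed):
        """Sound and complete against a literal re-check of the rules."""
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        calls = rng.integers(0, 3, size=(n, m)).astype(np.int16)
        calls[rng.random((n, m)) < 0.3] = MISSING
        matrix = make_matrix(calls)
        min_calls = int(rng.integers(0, n + 1))
        min_present = float(rng.uniform(0, 1))
        spec = FilterSpec(min_calls, min_present, "fuzz")

        keep_sites = [
            j for j in range(m)
            if (calls[:, j] != MISSING).sum() >= min_calls
        ]
        keep_samples = [
            i for i in range(n)
            if keep_sites
            and (calls[i, keep_sites] != MISSING).mean() >= min_present
        ]
        if not keep_sites or not keep_samples:
            with pytest.raises(EmptyFilterResult):
                filter_dataset(matrix, spec)
            return
        out, _ = filter_dataset(matrix, spec)
        assert out.marker_ids == [f"m{j}" for j in keep_sites]
        assert out.sample_ids == [f"s{i}" for i in keep_samples]


class TestPerSetSummary:
    def test_single_set_equals_marker_stat_means(self):
        from mdgkit.panel_design import compute_marker_stats

        calls = [[0, 1], [1, 2], [2, MISSING]]
        matrix = make_matrix(calls, labels=["G", "G", "G"])
        table = per_set_summary(matrix).set_index("set")
        stats = [
            compute_marker_stats(np.array(c), 2)
            for c in (np.array(calls)[:, 0], np.array(calls)[:, 1])
        ]
        assert table.loc["G", "pic"] == pytest.approx(
            np.mean([s.pic for s in stats])
        )
        assert table.loc["G", "maf"] == pytest.approx(
            np.mean([s.maf for s in stats])
        )

    def test_fully_called_matrix(self):
        matrix = make_matrix([[0, 1], [1, 2]], labels=["G", "G"])
        row = per_set_summary(matrix).set_index("set").loc["G"]
        assert row["proportion_missing"] == 0.0
        assert row["proportion_not_missing"] == 1.0

    def test_diverse_set_more_heterozygous_than_inbred_set(self):
        spec = PopulationSpec(
            n_markers=300,
            set_specs=[SetSpec("RSlike", 40, 0.15, 0.05),
                       SetSpec("ABLlike", 40, 0.05, 0.9)],
            seed=21,
        )
        matrix, _ = simulate_population(spec)
        table = per_set_summary(matrix).set_index("set")
        assert (
            table.loc["RSlike", "proportion_heterozygous"]
            > table.loc["ABLlike", "proportion_heterozygous"]
        )


class TestIbsDistance:
    def test_identical_samples_distance_zero(self):
        d = ibs_distance(make_matrix([[0, 1, 2], [0, 1, 2]]))
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        d = ibs_distance(make_matrix([[0, 0], [2, 2]]))
        assert d.values[0, 1] == 1.0

    def test_partial_sharing_hand_value(self):
        # markers: |0-1|/2 -> share 0.5; |2-2|/2 -> share 1 => dist 0.25
        d = ibs_distance(make_matrix([[0, 2], [1, 2]]))
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(6, 30)).astype(np.int16)
        calls[rng.random((6, 30)) < 0.2] = MISSING
        d = ibs_distance(make_matrix(calls))
        assert np.allclose(d.values, d.values.T, equal_nan=True)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_no_overlap_pair_is_missing(self):
        d = ibs_distance(make_matrix([[0, MISSING], [MISSING, 2]]))
        assert np.isnan(d.values[0, 1])
        assert d.has_missing


class TestClassicalMds:
    def test_collinear_points_need_one_axis(self):
        x = np.array([0.0, 1.0, 3.0])
        dist = np.abs(x[:, None] - x[None, :])
        r = classical_mds(DistanceMatrix(["a", "b", "c"], dist), k=2)
        assert r.variance_explained_percent[0] == pytest.approx(100.0)
        recovered = np.abs(
            r.coordinates[:, 0][:, None] - r.coordinates[:, 0][None, :]
        )
        assert np.allclose(recovered, dist, atol=1e-9)

    def test_equilateral_triangle_splits_evenly(self):
        dist = np.ones((3, 3)) - np.eye(3)
        r = classical_mds(DistanceMatrix(["a", "b", "c"], dist), k=2)
        assert r.variance_explained_percent[:2] == pytest.approx([50.0, 50.0])

    def test_euclidean_configuration_reproduced(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 3))
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        r = classical_mds(
            DistanceMatrix([f"p{i}" for i in range(6)], dist), k=3
        )
        dd = np.linalg.norm(
            r.coordinates[:, None, :] - r.coordinates[None, :, :], axis=2
        )
        assert np.allclose(dd, dist, atol=1e-9)

    def test_axis_variance_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(7, 3))
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        ids = [f"p{i}" for i in range(7)]
        base = classical_mds(DistanceMatrix(ids, dist), k=3)
        perm = rng.permutation(7)
        shuffled = classical_mds(
            DistanceMatrix([ids[i] for i in perm], dist[np.ix_(perm, perm)]), k=3
        )
        assert np.allclose(
            base.variance_explained_percent,
            shuffled.variance_explained_percent,
            atol=1e-9,
        )

    def test_missing_distances_error(self):
        dist = np.zeros((3, 3))
        dist[0, 1] = dist[1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            classical_mds(DistanceMatrix(["a", "b", "c"], dist), k=1)


def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """Distance matrix of a random binary tree with uniform(0.1, 1) branches."""
    import networkx as nx

    g = nx.Graph()
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        g.add_edge(a, nxt, weight=float(rng.uniform(0.1, 1.0)))
        g.add_edge(b, nxt, weight=float(rng.uniform(0.1, 1.0)))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        lengths = nx.single_source_dijkstra_path_length(g, i)
        for j in range(n_leaves):
            d[i, j] = lengths[j]
    return (d + d.T) / 2  # remove float round-off asymmetry


def tip_distance_error(tree, ids, d):
    td = tree.tip_tip_distances()
    order = [list(td.ids).index(s) for s in ids]
    return np.abs(np.asarray(td.data)[np.ix_(order, order)] - d).max()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_recovers_random_additive_trees_exactly(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(10):
            d = random_additive_matrix(n_leaves, rng)
            ids = [f"T{i}" for i in range(n_leaves)]
            tree = neighbor_joining(DistanceMatrix(ids, d))
            assert tip_distance_error(tree, ids, d) < 1e-9

    def test_matches_independent_nj_implementation(self):
        rng = np.random.default_rng(55)
        d = random_additive_matrix(7, rng)
        ids = [f"T{i}" for i in range(7)]
        ours = neighbor_joining(DistanceMatrix(ids, d))
        reference = skbio.tree.nj(
            skbio.DistanceMatrix(d, ids=ids)
        )
        ref_td = reference.tip_tip_distances()
        order = [list(ref_td.ids).index(s) for s in ids]
        ref_d = np.asarray(ref_td.data)[np.ix_(order, order)]
        assert tip_distance_error(ours, ids, ref_d) < 1e-9

    def test_identical_samples_become_zero_length_siblings(self):
        calls = np.array(
            [[0, 1, 2, 0], [0, 1, 2, 0], [2, 1, 0, 2], [2, 0, 0, 2]],
            dtype=np.int16,
        )
        matrix = make_matrix(calls)
        tree = neighbor_joining(ibs_distance(matrix))
        tips = {t.name: t for t in tree.tips()}
        assert tips["s0"].parent is tips["s1"].parent
        assert tips["s0"].length == 0.0 and tips["s1"].length == 0.0

    def test_incomplete_matrix_error(self):
        d = np.zeros((3, 3))
        d[0, 2] = d[2, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], d))


class TestExports:
    def test_newick_round_trip(self, tmp_path):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        text = p.read_text().strip()
        assert text.endswith(";")
        back = read_newick(p)
        assert {t.name for t in back.tips()} == {"A", "B", "C"}
        assert {t.name: t.length for t in back.tips()} == {
            "A": 1.0, "B": 1.0, "C": 3.0
        }

    def test_ordination_export_headers(self, tmp_path):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 2))
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        r = classical_mds(DistanceMatrix([f"p{i}" for i in range(5)], dist), k=2)
        p = tmp_path / "mds.csv"
        write_ordination(r, p)
        header = p.read_text().splitlines()[0]
        assert header.startswith("# variance explained:")
        percents = [float(tok.split("=")[1].rstrip("%"))
                    for tok in header.split(":", 1)[1].split(",")]
        assert sum(percents) <= 100.0 + 1e-9
        table = read_ordination(p)
        assert list(table.columns) == ["sample_id", "PC1", "PC2"]
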