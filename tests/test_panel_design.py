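"""PIC statistic, marker stats, candidate filters and panel selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdgkit.marker_catalog import MISSING, MarkerStats
from mdgkit.panel_design import (
    SelectionConfig,
    compute_marker_stats,
    compute_pic,
    filter_candidates,
    flank_spacing_filter,
    select_panel,
)

from conftest import make_marker


class TestComputePic:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0.5, 0.5), 0.375),          # symmetric biallelic maximum
            ((1.0, 0.0), 0.0),            # monomorphic
            ((0.9, 0.1), 0.1638),         # 1 - 0.82 - 2*0.81*0.01
        ],
    )
    def test_known_values(self, freqs, expected):
        assert compute_pic(freqs) == pytest.approx(expected, abs=1e-12)

    def test_rejects_unnormalized_frequencies(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compute_pic((0.6, 0.6))
        with pytest.raises(ValueError, match="non-negative"):
            compute_pic((1.5, -0.5))

    def test_biallelic_grid_maximum_is_0375_below_half(self):
        grid = np.arange(0, 1.0001, 0.001)
        values = [compute_pic((p, 1 - p)) for p in grid]
        assert max(values) == pytest.approx(0.375, abs=1e-12)
        assert grid[int(np.argmax(values))] == pytest.approx(0.5)
        assert max(values) < 0.5

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5).map(
            lambda ws: tuple(w / sum(ws) for w in ws)
        )
    )
    @settings(deadline=None)
    def test_never_exceeds_gene_diversity(self, freqs):
        gene_diversity = 1 - sum(p * p for p in freqs)
        assert compute_pic(freqs) <= gene_diversity + 1e-12


class TestComputeMarkerStats:
    def test_diploid_column(self):
        s = compute_marker_stats(np.array([0, 1, 2, 1]), 2)
        assert s.het_proportion == 0.5
        assert s.maf == 0.5
        assert s.missing_proportion == 0.0
        assert s.n_called == 4

    def test_missing_and_monomorphic(self):
        s = compute_marker_stats(np.array([0, 0, 0, MISSING]), 2)
        assert s.maf == 0.0
        assert s.missing_proportion == pytest.approx(0.25)
        assert s.pic == 0.0

    def test_tetraploid_dosages(self):
        # alt alleles: 4+3+2 = 9 of 12 -> alt freq 0.75, folded MAF 0.25
        s = compute_marker_stats(np.array([4, 3, 2]), 4)
        assert s.maf == pytest.approx(0.25)
        assert s.het_proportion == pytest.approx(2 / 3)

    def test_all_missing_column(self):
        s = compute_marker_stats(np.array([MISSING, MISSING]), 2)
        assert s.n_called == 0
        assert s.pic is None and s.maf is None


def _marker_with_stats(mid, pic=0.375, missing=0.0, het=0.0, **kw):
    m = make_marker(mid, **kw)
    m.stats = MarkerStats(
        pic=pic, maf=0.3, het_proportion=het, missing_proportion=missing,
        n_called=100,
    )
    return m


class TestFilterCandidates:
    def test_boundary_semantics(self):
        config = SelectionConfig()
        markers = [
            _marker_with_stats("too_missing", missing=0.25),
            _marker_with_stats("too_het", het=0.06),
            _marker_with_stats("at_pic_floor", pic=0.374),
            _marker_with_stats("below_pic", pic=0.3739),
            _marker_with_stats("at_het_bound", het=0.05),
        ]
        passing, ledger = filter_candidates(markers, config)
        assert passing == ["at_pic_floor", "at_het_bound"]
        assert ledger.rejected_missing == 1
        assert ledger.rejected_het == 1
        assert ledger.rejected_pic == 1

    def test_first_failing_rule_attribution(self):
        # fails every rule; attributed to 'missing' (first in fixed order)
        markers = [_marker_with_stats("m", pic=0.1, missing=0.5, het=0.5)]
        _, ledger = filter_candidates(markers, SelectionConfig())
        assert ledger.rejected_ids["m"] == "missing"

    def test_idempotent(self):
        config = SelectionConfig()
        markers = [
            _marker_with_stats(f"m{i}", pic=0.3 + 0.01 * i) for i in range(12)
        ]
        passing1, _ = filter_candidates(markers, config)
        survivors = [m for m in markers if m.marker_id in set(passing1)]
        passing2, ledger2 = filter_candidates(survivors, config)
        assert passing2 == passing1
        assert ledger2.n_passed == ledger2.n_input


class TestFlankSpacingFilter:
    def test_close_pair_both_crowded(self):
        markers = [make_marker("a", pos=100), make_marker("b", pos=250)]
        isolated, crowded = flank_spacing_filter(markers, 200)
        assert isolated == []
        assert set(crowded) == {"a", "b"}

    def test_distant_pair_isolated(self):
        markers = [make_marker("a", pos=100), make_marker("b", pos=600)]
        isolated, _ = flank_spacing_filter(markers, 200)
        assert set(isolated) == {"a", "b"}

    def test_rule_is_per_chromosome(self):
        markers = [
            make_marker("a", "Arahy.01", 100), make_marker("b", "Arahy.02", 100)
        ]
        isolated, crowded = flank_spacing_filter(markers, 200)
        assert set(isolated) == {"a", "b"} and crowded == []

    def test_window_boundary_inclusive(self):
        markers = [make_marker("a", pos=100), make_marker("b", pos=300)]
        _, crowded = flank_spacing_filter(markers, 200)
        assert set(crowded) == {"a", "b"}


class TestSelectPanel:
    def test_top_pic_without_balancing(self):
        markers = [
            _marker_with_stats(f"m{i}", pic=0.30 + 0.005 * i, pos=1000 * (i + 1))
            for i in range(10)
        ]
        config = SelectionConfig(target_size=5, reserve_size=3)
        sel = select_panel(markers, config)
        assert sel.selected_ids == ["m9", "m8", "m7", "m6", "m5"]
        assert sel.reserve_ids == ["m4", "m3", "m2"]

    def test_trait_markers_bypass_pic_ranking(self):
        markers = [
            _marker_with_stats(f"m{i}", pic=0.37, pos=1000 * (i + 1))
            for i in range(6)
        ]
        trait = [_marker_with_stats("trait1", pic=0.01, pos=99_000),
                 _marker_with_stats("trait2", pic=0.02, pos=98_000)]
        sel = select_panel(markers, SelectionConfig(target_size=5), trait)
        assert set(sel.trait_ids) == {"trait1", "trait2"}
        assert set(sel.trait_ids) <= set(sel.selected_ids)
        assert len(sel.selected_ids) == 5

    def test_tie_broken_by_chromosome_then_position(self):
        a = _marker_with_stats("late", pic=0.375, chrom="Arahy.02", pos=50)
        b = _marker_with_stats("early", pic=0.375, chrom="Arahy.01", pos=900)
        c = _marker_with_stats("top", pic=0.376, chrom="Arahy.05", pos=10)
        sel = select_panel([a, b, c], SelectionConfig(target_size=2))
        assert sel.selected_ids == ["top", "early"]

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        markers = [
            _marker_with_stats(
                f"m{i}", pic=float(rng.choice([0.374, 0.375, 0.376])),
                chrom=f"Arahy.{1 + i % 4:02d}", pos=int(rng.integers(1, 10**6)),
            )
            for i in range(40)
        ]
        config = SelectionConfig(target_size=10, reserve_size=5,
                                 per_chromosome_balancing=True)
        baseline = select_panel(markers, config)
        for seed in range(3):
            shuffled = list(markers)
            np.random.default_rng(seed).shuffle(shuffled)
            again = select_panel(shuffled, config)
            assert again.selected_ids == baseline.selected_ids
            assert again.reserve_ids == baseline.reserve_ids

    def test_balancing_apportions_by_availability(self):
        markers = [
            _marker_with_stats(f"a{i}", pic=0.38, chrom="Arahy.01", pos=10_000 * (i + 1))
            for i in range(8)
        ] + [
            _marker_with_stats(f"b{i}", pic=0.50 - 0.01 * i, chrom="Arahy.02",
                               pos=10_000 * (i + 1))
            for i in range(8)
        ]
        config = SelectionConfig(target_size=8, per_chromosome_balancing=True)
        sel = select_panel(markers, config)
        assert sel.per_chromosome == {"Arahy.01": 4, "Arahy.02": 4}

    def test_fewer_candidates_than_target_selects_all(self):
        markers = [_marker_with_stats("m1"), _marker_with_stats("m2", pos=9000)]
        sel = select_panel(markers, SelectionConfig(target_size=10))
        assert set(sel.selected_ids) == {"m1", "m2"}
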