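import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynameth.errors import ValidationError
from dynameth.genomic_io import GenomicInterval, SampleCallSet
from dynameth.panel_design import Panel
from dynameth.dmr_caller import (DMR, TileMatrix, aggregate_tile_counts,
                                 bh_adjust, call_pairwise_dmrs,
                                 coverage_filter, dynamic_fraction,
                                 fisher_exact, make_tiles, match_dmr_sets,
                                 pairwise_tests)


def fisher_oracle(a, b):
    """Exhaustive hypergeometric enumeration in exact rational arithmetic."""
    am, au = a
    bm, bu = b
    r1, r2, c1 = am + au, bm + bu, am + bm
    obs = math.comb(r1, am) * math.comb(r2, bm)
    num = sum(w for k in range(max(0, c1 - r2), min(r1, c1) + 1)
              if (w := math.comb(r1, k) * math.comb(r2, c1 - k)) <= obs)
    return Fraction(num, math.comb(r1 + r2, c1))


def bh_oracle(p):
    """Hand-applied step-up formula: q_(i) = min_{j>=i} p_(j)*m/j, capped."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestMakeTiles:
    def test_grid_rule_on_offset_region(self):
        panel = Panel.from_intervals([GenomicInterval("chr1", 250, 450)])
        assert make_tiles(panel, 200) == [GenomicInterval("chr1", 200, 400),
                                          GenomicInterval("chr1", 400, 600)]

    def test_aligned_region_single_tile(self):
        panel = Panel.from_intervals([GenomicInterval("chr1", 200, 400)])
        assert make_tiles(panel, 200) == [GenomicInterval("chr1", 200, 400)]

    def test_empty_panel_and_bad_size(self):
        assert make_tiles(Panel([], 0, 0)) == []
        with pytest.raises(ValidationError):
            make_tiles(Panel([], 0, 0), tile_size=0)

    def test_overlapping_regions_unique_tiles(self):
        panel = [GenomicInterval("chr1", 100, 300),
                 GenomicInterval("chr1", 250, 380)]
        tiles = make_tiles(panel, 200)
        assert tiles == [GenomicInterval("chr1", 0, 200),
                         GenomicInterval("chr1", 200, 400)]


class TestAggregate:
    def _matrix(self, calls, tiles=None):
        df = pd.DataFrame(calls, columns=["chrom", "pos", "meth_reads",
                                          "total_reads"])
        cs = SampleCallSet("s1", df)
        if tiles is None:
            tiles = [GenomicInterval("chr1", 0, 200)]
        return aggregate_tile_counts(tiles, [cs])

    def test_single_cpg(self):
        mat = self._matrix([("chr1", 10, 3, 10)])
        assert mat.levels[0, 0] == pytest.approx(0.3)

    def test_pooled_equals_weighted_mean(self):
        mat = self._matrix([("chr1", 10, 3, 10), ("chr1", 20, 27, 30)])
        assert mat.levels[0, 0] == pytest.approx(0.75)
        assert mat.levels[0, 0] == pytest.approx(
            np.average([0.3, 0.9], weights=[10, 30]))

    def test_empty_tile_is_missing(self):
        mat = self._matrix([("chr1", 500, 3, 10)],
                           tiles=[GenomicInterval("chr1", 0, 200),
                                  GenomicInterval("chr1", 400, 600)])
        assert np.isnan(mat.levels[0, 0])
        assert mat.levels[1, 0] == pytest.approx(0.3)

    def test_pooled_ratio_identity_random(self, rng):
        pos = np.sort(rng.choice(np.arange(0, 2000, 2), 300, replace=False))
        total = rng.integers(1, 80, size=300)
        meth = rng.binomial(total, rng.uniform(0, 1, size=300))
        df = pd.DataFrame({"chrom": "chr1", "pos": pos, "meth_reads": meth,
                           "total_reads": total})
        tiles = make_tiles([GenomicInterval("chr1", 0, 2000)], 200)
        mat = aggregate_tile_counts(tiles, [SampleCallSet("s", df)])
        for i, t in enumerate(mat.tiles):
            inside = (pos >= t.start) & (pos < t.end)
            if inside.sum():
                expected = np.average(meth[inside] / total[inside],
                                      weights=total[inside])
                assert mat.levels[i, 0] == pytest.approx(expected, abs=1e-12)


class TestCoverageFilter:
    def _mat(self, totals):
        totals = np.asarray(totals)[None, :]
        tiles = [GenomicInterval("chr1", 0, 200)]
        return TileMatrix(tiles, [f"s{i}" for i in range(totals.shape[1])],
                          np.zeros_like(totals), totals)

    def test_seven_of_ten_retained(self):
        mat = self._mat([11] * 7 + [5] * 3)
        assert coverage_filter(mat).n_tiles == 1

    def test_six_of_ten_dropped(self):
        mat = self._mat([11] * 6 + [5] * 4)
        assert coverage_filter(mat).n_tiles == 0

    def test_exactly_ten_reads_does_not_count(self):
        mat = self._mat([10] * 10)
        assert coverage_filter(mat).n_tiles == 0
        assert coverage_filter(self._mat([11] * 10)).n_tiles == 1


class TestFisherExact:
    def test_identical_margins_give_one(self):
        assert fisher_exact((5, 5), (5, 5)) == 1.0

    def test_enumerated_extreme_tables(self):
        assert fisher_exact((10, 0), (0, 10)) == pytest.approx(
            2 / 184756, abs=1e-15)
        assert fisher_exact((9, 1), (1, 9)) == pytest.approx(
            202 / 184756, abs=1e-15)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact((-1, 5), (2, 3))

    def test_agrees_with_exact_oracle_random_tables(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 61))
            r1 = int(rng.integers(1, n))
            r2 = n - r1
            if r2 < 1:
                continue
            am = int(rng.integers(0, r1 + 1))
            bm = int(rng.integers(0, r2 + 1))
            a, b = (am, r1 - am), (bm, r2 - bm)
            assert abs(fisher_exact(a, b) - float(fisher_oracle(a, b))) < 1e-12

    @given(r1=st.integers(1, 40), r2=st.integers(1, 40),
           am_frac=st.floats(0, 1), bm_frac=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_scipy(self, r1, r2, am_frac, bm_frac):
        from scipy.stats import fisher_exact as scipy_fisher

        am, bm = int(am_frac * r1), int(bm_frac * r2)
        table = [[am, r1 - am], [bm, r2 - bm]]
        ours = fisher_exact((am, r1 - am), (bm, r2 - bm))
        theirs = scipy_fisher(table).pvalue
        assert ours == pytest.approx(theirs, rel=1e-7, abs=1e-12)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_collapse(self):
        q = bh_adjust([0.2] * 5)
        assert np.allclose(q, 0.2)

    def test_hand_applied_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_monotone_idempotent(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        # monotone along sorted p
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        # re-application never decreases q (full idempotence fails in
        # general: p = (0, 0.5, 1) -> q = (0, 0.75, 1) -> (0, 1, 1))
        assert np.all(bh_adjust(q) >= q - 1e-12)


def _two_sample_matrix(tile_specs):
    """tile_specs: list of (start, (meth_a, tot_a), (meth_b, tot_b))."""
    tiles = [GenomicInterval("chr1", s, s + 200) for s, _, _ in tile_specs]
    meth = np.array([[a[0], b[0]] for _, a, b in tile_specs])
    total = np.array([[a[1], b[1]] for _, a, b in tile_specs])
    return TileMatrix(tiles, ["A", "B"], meth, total)


class TestCallPairwiseDmrs:
    def test_thresholds_on_q_and_delta(self):
        # one extreme tile (tiny q, delta 1.0) and one with delta 0.2 only
        mat = _two_sample_matrix([
            (0, (100, 100), (0, 100)),
            (1000, (50, 100), (30, 100)),
        ])
        dmrs = call_pairwise_dmrs(mat, "A", "B")
        assert len(dmrs) == 1 and dmrs[0].interval.start == 0
        assert dmrs[0].direction == "hyper"

    def test_merge_below_400bp_gap(self):
        mat = _two_sample_matrix([
            (0, (0, 100), (100, 100)),
            (400, (0, 100), (100, 100)),   # gap 200 < 400 -> merge
        ])
        dmrs = call_pairwise_dmrs(mat, "A", "B")
        assert len(dmrs) == 1
        assert (dmrs[0].interval.start, dmrs[0].interval.end) == (0, 600)
        assert dmrs[0].direction == "hypo"

    def test_gap_of_exactly_400_is_not_merged(self):
        mat = _two_sample_matrix([
            (0, (0, 100), (100, 100)),
            (600, (0, 100), (100, 100)),   # gap 400, not < 400
        ])
        dmrs = call_pairwise_dmrs(mat, "A", "B")
        assert len(dmrs) == 2

    def test_symmetric_in_pair_up_to_direction(self):
        mat = _two_sample_matrix([
            (0, (100, 100), (0, 100)),
            (2000, (0, 100), (100, 100)),
        ])
        fwd = call_pairwise_dmrs(mat, "A", "B")
        rev = call_pairwise_dmrs(mat, "B", "A")
        assert [(d.interval.start, d.interval.end) for d in fwd] == \
            [(d.interval.start, d.interval.end) for d in rev]
        flip = {"hypo": "hyper", "hyper": "hypo"}
        assert [d.direction for d in rev] == [flip[d.direction] for d in fwd]

    def test_unknown_sample_rejected(self):
        mat = _two_sample_matrix([(0, (1, 10), (2, 10))])
        with pytest.raises(ValidationError):
            call_pairwise_dmrs(mat, "A", "C")

    def test_zero_coverage_tile_skipped(self):
        mat = _two_sample_matrix([(0, (0, 100), (0, 0))])
        assert pairwise_tests(mat, "A", "B") == []


class TestDynamicFraction:
    def test_identical_samples_zero(self):
        mat = _two_sample_matrix([(0, (30, 60), (30, 60)),
                                  (1000, (10, 50), (10, 50))])
        assert dynamic_fraction(mat) == 0.0

    def test_all_extreme_tiles_one(self):
        mat = _two_sample_matrix([(s, (100, 100), (0, 100))
                                  for s in range(0, 5000, 1000)])
        assert dynamic_fraction(mat) == 1.0


class TestMatchDmrSets:
    def _dmr(self, start, end):
        return DMR(GenomicInterval("chr1", start, end), "A", "B", "hypo",
                   [], 0.01)

    def test_overlap_and_distance_boundaries(self):
        ref = [GenomicInterval("chr1", 1000, 1200)]
        overlap = self._dmr(1100, 1300)
        near = self._dmr(1450, 1500)      # 250 bp from ref end
        far = self._dmr(1501, 1600)       # 301 bp away
        shared, query_only = match_dmr_sets([overlap, near, far], ref, 300)
        assert shared == [overlap, near]
        assert query_only == [far]

    def test_empty_reference_all_query_only(self):
        q = [self._dmr(0, 200)]
        shared, query_only = match_dmr_sets(q, [], 300)
        assert shared == [] and query_only == q
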