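import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cncr.annotation import (
    AnnotationSet,
    annotate,
    call_cncr,
    call_constrained,
    call_nonconserved,
    compute_cnc,
    derive_nonconserved_rank,
    export_ldsc_annot,
    partition_deciles,
    rank_bins,
    score_bins,
)
from cncr.tracks import GenomeLayout

from conftest import bins_frame


def _layout_for(bins: pd.DataFrame) -> GenomeLayout:
    lengths = {c: int(sub["end"].max()) for c, sub in bins.groupby("chrom", sort=False)}
    return GenomeLayout.from_lengths(lengths)


# ---------------------------------------------------------------------------
# ranking and the CNC score
# ---------------------------------------------------------------------------

class TestRanks:
    def test_lower_cdts_gets_higher_constraint_rank(self):
        df = pd.DataFrame({"chrom": "chr1", "start": [0, 10, 20],
                           "end": [10, 20, 30], "cdts": [-5.0, -1.0, -3.0],
                           "cons": [0.0, 1.0, 0.5]})
        ranked = rank_bins(df)
        assert ranked["rank_constraint"].tolist() == [3, 1, 2]
        assert ranked["rank_conservation"].tolist() == [1, 3, 2]

    def test_ties_get_midranks(self):
        df = pd.DataFrame({"chrom": "chr1", "start": [0, 10], "end": [10, 20],
                           "cdts": [0.0, 1.0], "cons": [0.2, 0.2]})
        ranked = rank_bins(df)
        assert ranked["rank_conservation"].tolist() == [1.5, 1.5]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_bins(pd.DataFrame(columns=["cdts", "cons"]))


class TestComputeCnc:
    def test_twofold_rank_disparity_scores_one(self):
        assert compute_cnc(2_000_000, 1_000_000) == pytest.approx(1.0)

    def test_equal_ranks_score_zero(self):
        assert compute_cnc(7, 7) == 0.0

    def test_eightfold_lower_constraint(self):
        assert compute_cnc(1_000, 8_000) == pytest.approx(-3.0)

    def test_nonpositive_rank_rejected(self):
        with pytest.raises(ValueError):
            compute_cnc(0, 5)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 10**6), st.integers(1, 10**6))
    def test_antisymmetry(self, a, b):
        assert compute_cnc(a, b) == pytest.approx(-compute_cnc(b, a))

    def test_monotone_in_constraint_rank(self):
        ranks = np.arange(1, 2000)
        scores = compute_cnc(ranks, np.full_like(ranks, 700))
        assert (np.diff(scores) > 0).all()

    def test_null_median_centred_at_zero(self):
        rng = np.random.default_rng(2024)
        n = 100_000
        rc = rng.permutation(n) + 1
        rn = rng.permutation(n) + 1
        assert abs(np.median(compute_cnc(rc, rn))) <= 0.02


# ---------------------------------------------------------------------------
# calling: brute-force oracles
# ---------------------------------------------------------------------------

def oracle_select_top(bins: pd.DataFrame, layout: GenomeLayout, fraction: float):
    """Reference top-k selection: sort then take floor(f*N) rows."""
    k = int(np.floor(fraction * len(bins)))
    order = {c: i for i, c in enumerate(layout.chrom_names)}
    idx = sorted(range(len(bins)),
                 key=lambda i: (-bins["rank_constraint"].iat[i],
                                order[bins["chrom"].iat[i]], bins["start"].iat[i]))
    flags = np.zeros(len(bins), dtype=bool)
    flags[idx[:k]] = True
    return flags


def oracle_merge(bins: pd.DataFrame, flags, layout: GenomeLayout) -> list:
    """Reference flag-then-merge: walk sorted flagged bins and join abutters."""
    order = {c: i for i, c in enumerate(layout.chrom_names)}
    rows = sorted(((bins["chrom"].iat[i], bins["start"].iat[i], bins["end"].iat[i])
                   for i in np.flatnonzero(flags)),
                  key=lambda r: (order[r[0]], r[1]))
    merged: list[list] = []
    for c, s, e in rows:
        if merged and merged[-1][0] == c and merged[-1][2] == s:
            merged[-1][2] = e
        else:
            merged.append([c, s, e])
    return [tuple(m) for m in merged]


class TestCallConstrained:
    def test_eighth_of_thousand(self):
        rng = np.random.default_rng(0)
        bins = bins_frame(1000, rng)
        flags, _ = call_constrained(rank_bins(bins), _layout_for(bins))
        assert flags.sum() == 125

    def test_floor_rule_small_n(self):
        rng = np.random.default_rng(1)
        bins = bins_frame(8, rng)
        flags, _ = call_constrained(rank_bins(bins), _layout_for(bins))
        assert flags.sum() == 1

    def test_tie_straddling_cutoff_is_deterministic(self):
        # 6 bins, four-way tie at the most constrained value, k = 3
        bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(6) * 10,
                             "end": np.arange(1, 7) * 10,
                             "cdts": [-1.0, -1.0, 0.0, -1.0, -1.0, 1.0],
                             "cons": np.linspace(0, 1, 6)})
        layout = _layout_for(bins)
        ranked = rank_bins(bins)
        flags1, iv1 = call_constrained(ranked, layout, fraction=0.5)
        flags2, _ = call_constrained(ranked, layout, fraction=0.5)
        assert flags1.sum() == 3
        assert (flags1 == flags2).all()
        # positional tie-break: the earliest tied bins win
        assert flags1.tolist() == [True, True, False, True, False, False]
        np.testing.assert_array_equal(flags1, oracle_select_top(ranked, layout, 0.5))

    def test_fraction_validated(self):
        rng = np.random.default_rng(2)
        bins = rank_bins(bins_frame(20, rng))
        with pytest.raises(ValueError):
            call_constrained(bins, _layout_for(bins), fraction=0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bins = bins_frame(400, rng, chroms=("chr1", "chr2"))
        # force ties so the positional tie-break is exercised
        bins["cdts"] = np.round(bins["cdts"], 1)
        ranked = rank_bins(bins)
        layout = _layout_for(bins)
        flags, intervals = call_constrained(ranked, layout)
        np.testing.assert_array_equal(flags, oracle_select_top(ranked, layout, 0.125))
        assert list(intervals.itertuples(index=False, name=None)) == \
            oracle_merge(ranked, flags, layout)


class TestCallCncr:
    def test_adjacent_qualifying_bins_merge(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": [0, 10, 20],
                             "end": [10, 20, 30], "cnc": [1.5, 1.0, 0.2]})
        layout = GenomeLayout.from_lengths({"chr1": 30})
        flags, intervals = call_cncr(bins, np.array([True, True, True]), layout)
        assert flags.tolist() == [True, True, False]
        assert intervals.iloc[0].tolist() == ["chr1", 0, 20]

    def test_threshold_is_inclusive_so_just_below_excluded(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [10], "cnc": [0.99]})
        layout = GenomeLayout.from_lengths({"chr1": 10})
        flags, intervals = call_cncr(bins, np.array([True]), layout)
        assert not flags.any() and len(intervals) == 0

    def test_cncr_subset_of_constrained(self, small_annotated):
        _, _, _, scored, _ = small_annotated
        assert not (scored["cncr"] & ~scored["constrained"]).any()
        assert scored["constrained"].sum() == int(np.floor(0.125 * len(scored)))


class TestCallNonconserved:
    def test_integer_threshold(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(4) * 10,
                             "end": np.arange(1, 5) * 10,
                             "rank_conservation": [1.0, 2.0, 3.0, 4.0]})
        layout = GenomeLayout.from_lengths({"chr1": 40})
        flags, _ = call_nonconserved(bins, layout, rank_threshold=2)
        assert flags.tolist() == [True, True, False, False]

    def test_zero_threshold_empty(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [10],
                             "rank_conservation": [1.0]})
        layout = GenomeLayout.from_lengths({"chr1": 10})
        flags, intervals = call_nonconserved(bins, layout, rank_threshold=0)
        assert not flags.any() and len(intervals) == 0

    def test_derive_matches_hand_computation(self):
        rng = np.random.default_rng(9)
        bins = bins_frame(500, rng)
        scored = score_bins(bins)
        thr = derive_nonconserved_rank(scored, tol=0.25)
        # hand oracle: Q1 of cons among bins near cnc=1, then count-based midrank
        window = scored.loc[(scored["cnc"] - 1).abs() <= 0.25, "cons"]
        q1 = np.quantile(window, 0.25)
        cons = scored["cons"].to_numpy()
        expected = (cons < q1).sum() + ((cons == q1).sum() + 1) / 2 \
            if (cons == q1).any() else (cons < q1).sum() + 0.5
        assert thr == pytest.approx(expected)

    def test_derive_empty_window_advises_larger_tol(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": [0, 10], "end": [10, 20],
                             "cdts": [0.0, 1.0], "cons": [0.9, 0.1]})
        scored = score_bins(bins)
        with pytest.raises(ValueError, match="tol"):
            derive_nonconserved_rank(scored, tol=1e-9)


class TestDeciles:
    @staticmethod
    def _scored(n, rng):
        bins = bins_frame(n, rng)
        return score_bins(bins)

    def test_twenty_bins_ten_pairs_with_top_cnc_high(self):
        rng = np.random.default_rng(3)
        scored = self._scored(20, rng)
        layout = _layout_for(scored)
        labels = partition_deciles(scored, np.ones(20, dtype=bool), layout)
        assert (labels.value_counts() == 2).all()
        top2 = scored["cnc"].nlargest(2).index
        assert (labels.loc[top2] == "90-100").all()

    def test_23_bins_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(4)
        scored = self._scored(23, rng)
        labels = partition_deciles(scored, np.ones(23, dtype=bool), _layout_for(scored))
        sizes = labels.value_counts()
        assert sorted(sizes) == [2] * 7 + [3] * 3

    def test_all_equal_cnc_is_deterministic(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(10) * 10,
                             "end": np.arange(1, 11) * 10,
                             "cnc": np.zeros(10)})
        layout = GenomeLayout.from_lengths({"chr1": 100})
        a = partition_deciles(bins, np.ones(10, dtype=bool), layout)
        b = partition_deciles(bins, np.ones(10, dtype=bool), layout)
        assert (a == b).all()
        # positional tie-break: labels follow genomic order
        assert a.tolist() == [f"{10*i}-{10*(i+1)}" for i in range(10)]

    def test_fewer_than_ten_rejected(self):
        rng = np.random.default_rng(5)
        scored = self._scored(9, rng)
        with pytest.raises(ValueError):
            partition_deciles(scored, np.ones(9, dtype=bool), _layout_for(scored))


class TestLdscExport:
    annotations = AnnotationSet(
        cncr=pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]}),
        constrained=pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [30]}),
        nonconserved=pd.DataFrame(columns=["chrom", "start", "end"]))

    def test_position_inside_half_open_interval(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [15], "rsid": ["rs1"]})
        out = export_ldsc_annot(self.annotations, snps)
        assert out["CNCR"].tolist() == [1]

    def test_position_just_past_end_excluded(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [21], "rsid": ["rs1"]})
        out = export_ldsc_annot(self.annotations, snps)
        assert out["CNCR"].tolist() == [0]
        assert out["constrained"].tolist() == [1]  # pos 21 -> 0-based 20 in [10,30)

    def test_empty_category_all_zero_and_unknown_chrom_warns(self):
        snps = pd.DataFrame({"chrom": ["chr1", "chrZ"], "pos": [15, 5],
                             "rsid": ["rs1", "rs2"]})
        with pytest.warns(UserWarning, match="chrZ"):
            out = export_ldsc_annot(self.annotations, snps)
        assert out["nonconserved"].tolist() == [0, 0]
        assert out.loc[1].tolist() == [0, 0, 0]


def test_planted_blocks_recovered_and_controls_never_called(full_annotated):
    """End-to-end: planted extreme-constraint/low-conservation blocks are
    called CNCR at >=95% bp sensitivity; constrained-and-conserved control
    blocks are never called."""
    from cncr._intervals import overlap_bp

    _, _, _, truth, scored, ann = full_annotated
    planted = truth.cncr_blocks.copy()
    planted["bid"] = np.arange(len(planted))
    got = overlap_bp(planted, ann.cncr, by="bid").sum()
    total = (planted["end"] - planted["start"]).sum()
    assert got / total >= 0.95
    controls = truth.control_blocks.copy()
    controls["bid"] = np.arange(len(controls))
    assert overlap_bp(controls, ann.cncr, by="bid").sum() == 0
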