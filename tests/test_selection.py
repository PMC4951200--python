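import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chipdiff import (
    SelectionParams,
    apply_signal_floor,
    assign_bins,
    evaluate_against_truth,
    merge_selected,
    select_central,
    select_extreme_in_bin,
    select_windows,
)
from chipdiff.selection import ABin

from conftest import scores_frame


def frame_with_a(a_values, d_values=None):
    a = np.asarray(a_values, dtype=float)
    d = np.zeros_like(a) if d_values is None else np.asarray(d_values, dtype=float)
    n = len(a)
    return pd.DataFrame(
        {
            "chrom": "chrI",
            "start": np.arange(n) * 250,
            "end": np.arange(n) * 250 + 500,
            "y_a": 1.0,
            "y_b": 1.0,
            "D": d,
            "A": a,
            "defined": True,
        }
    )


class TestSignalFloor:
    def test_ten_percent_floor_on_distinct_values(self):
        scores = frame_with_a(np.arange(100.0))
        eligible, threshold = apply_signal_floor(scores, 0.10)
        assert threshold == pytest.approx(9.9)
        assert len(eligible) == 90
        assert scores.loc[eligible, "A"].min() == 10.0

    def test_identical_a_values_retain_nothing(self):
        scores = frame_with_a(np.full(20, 3.0))
        eligible, threshold = apply_signal_floor(scores, 0.10)
        assert threshold == 3.0 and len(eligible) == 0

    def test_zero_quantile_still_strict(self):
        scores = frame_with_a([1.0, 2.0, 3.0])
        eligible, _ = apply_signal_floor(scores, 0.0)
        assert set(scores.loc[eligible, "A"]) == {2.0, 3.0}

    def test_undefined_windows_excluded_from_quantile(self):
        scores = frame_with_a(np.arange(10.0))
        scores.loc[0:4, "defined"] = False
        eligible, threshold = apply_signal_floor(scores, 0.10)
        assert threshold == pytest.approx(np.quantile(np.arange(5.0, 10.0), 0.10))

    def test_no_defined_windows_is_error(self):
        scores = frame_with_a([1.0, 2.0])
        scores["defined"] = False
        with pytest.raises(ValueError, match="defined"):
            apply_signal_floor(scores)

    def test_retained_fraction_matches_quantile(self, rng):
        scores = frame_with_a(rng.normal(size=2000))
        eligible, _ = apply_signal_floor(scores, 0.10)
        assert abs(len(eligible) / 2000 - 0.9) <= 1 / 2000


class TestAssignBins:
    def test_anchored_bins_with_max_included(self):
        scores = frame_with_a([5.00, 5.12, 5.21, 5.35])
        bins = assign_bins(scores, scores.index.to_numpy(), 0.1, min_bin_members=1)
        assert [(round(b.lo, 10), round(b.hi, 10)) for b in bins] == [
            (5.0, 5.1), (5.1, 5.2), (5.2, 5.3), (5.3, 5.4),
        ]
        assert all(len(b) == 1 for b in bins)

    def test_single_window_single_bin(self):
        scores = frame_with_a([7.3])
        bins = assign_bins(scores, scores.index.to_numpy(), 0.1)
        assert len(bins) == 1 and list(bins[0].members) == [0]

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=2.0, size=10_000)
        scores = frame_with_a(a)
        eligible = scores.index.to_numpy()
        bins = assign_bins(scores, eligible, 0.1, min_bin_members=1)
        seen = np.concatenate([b.members for b in bins])
        assert len(seen) == len(eligible)
        assert set(seen) == set(eligible)
        for b in bins:
            vals = scores.loc[b.members, "A"]
            assert (vals >= b.lo - 1e-12).all()
            # right-closure only allowed for the global maximum
            assert ((vals < b.hi) | np.isclose(vals, a.max())).all()

    def test_sparse_bins_merged_into_nearest_nonsparse(self):
        # 40 values near 0, 2 isolated high values
        a = np.concatenate([np.linspace(0, 0.09, 40), [1.0, 2.0]])
        scores = frame_with_a(a)
        bins = assign_bins(scores, scores.index.to_numpy(), 0.1, min_bin_members=10)
        assert len(bins) == 1
        assert len(bins[0]) == 42

    def test_empty_eligible_is_error(self):
        scores = frame_with_a([1.0])
        with pytest.raises(ValueError):
            assign_bins(scores, np.array([], dtype=int), 0.1)


class TestSelectExtreme:
    def test_lower_tail_of_100_distinct(self, rng):
        d = rng.permutation(np.arange(100.0))
        scores = frame_with_a(np.zeros(100), d)
        bin = ABin(0.0, 0.1, scores.index.to_numpy())
        picked = select_extreme_in_bin(bin, scores, 0.03, "lower")
        assert sorted(scores.loc[picked, "D"]) == [0.0, 1.0, 2.0]

    def test_upper_tail_symmetric(self, rng):
        d = rng.permutation(np.arange(100.0))
        scores = frame_with_a(np.zeros(100), d)
        bin = ABin(0.0, 0.1, scores.index.to_numpy())
        picked = select_extreme_in_bin(bin, scores, 0.03, "upper")
        assert sorted(scores.loc[picked, "D"]) == [97.0, 98.0, 99.0]

    def test_ties_at_threshold_included(self):
        d = np.array([-1.0, -1.0] + list(range(32)), dtype=float)
        scores = frame_with_a(np.zeros(len(d)), d)
        bin = ABin(0.0, 0.1, scores.index.to_numpy())
        picked = select_extreme_in_bin(bin, scores, 0.03, "lower")
        assert list(picked) == [0, 1]

    def test_selected_at_least_as_extreme_as_unselected(self, rng):
        d = rng.normal(size=500)
        scores = frame_with_a(np.zeros(500), d)
        bin = ABin(0.0, 0.1, scores.index.to_numpy())
        picked = set(select_extreme_in_bin(bin, scores, 0.05, "lower"))
        rest = set(scores.index) - picked
        assert scores.loc[list(picked), "D"].max() <= scores.loc[list(rest), "D"].min()

    def test_alpha_at_half_rejected_by_params(self):
        with pytest.raises(ValueError):
            SelectionParams(alpha=0.5)


class TestSelectCentral:
    def test_middle_six_of_ten(self, rng):
        d = rng.permutation(np.arange(10.0))
        scores = frame_with_a(np.zeros(10), d)
        picked = select_central(scores, scores.index.to_numpy(), 0.6)
        assert sorted(scores.loc[picked, "D"]) == [2, 3, 4, 5, 6, 7]

    def test_full_fraction_keeps_everything(self, rng):
        d = rng.normal(size=50)
        scores = frame_with_a(np.zeros(50), d)
        picked = select_central(scores, scores.index.to_numpy(), 1.0)
        assert len(picked) == 50

    def test_tiny_fraction_keeps_at_most_median_ties(self, rng):
        d = rng.permutation(np.arange(11.0))
        scores = frame_with_a(np.zeros(11), d)
        picked = select_central(scores, scores.index.to_numpy(), 0.01)
        assert set(scores.loc[picked, "D"]).issubset({5.0})

    def test_retains_fraction_within_two_over_m(self, rng):
        m = 4001
        d = rng.normal(size=m)
        scores = frame_with_a(np.zeros(m), d)
        picked = select_central(scores, scores.index.to_numpy(), 0.6)
        assert abs(len(picked) / m - 0.6) <= 2 / m


class TestMergeSelected:
    def test_overlapping_and_disjoint_runs(self):
        scores = scores_frame([1, 1, 0, 0, 1, 1], [2, 2, 1, 1, 2, 2])
        # windows: [0,500) [250,750) [500,1000) [750,1250) [1000,1500) [1250,1750)
        regions = merge_selected(scores, np.array([0, 1, 4]))
        assert list(map(tuple, regions[["start", "end"]].to_numpy())) == [
            (0, 750), (1000, 1500),
        ]
        assert regions.iloc[0]["member_windows"] == [0, 1]

    def test_book_ended_windows_merge(self):
        scores = scores_frame([1, 1, 1], [1, 1, 1], width=500, step=500)
        regions = merge_selected(scores, np.array([0, 1]))
        assert len(regions) == 1
        assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (0, 1000)

    def test_single_window_region(self):
        scores = scores_frame([1], [3])
        regions = merge_selected(scores, np.array([0]))
        assert len(regions) == 1
        assert regions.iloc[0]["extreme_D"] == pytest.approx(-1.0)

    def test_windows_on_different_chromosomes_never_merge(self):
        scores = pd.concat(
            [scores_frame([1], [1], chrom="chrI"), scores_frame([1], [1], chrom="chrII")],
            ignore_index=True,
        )
        regions = merge_selected(scores, np.array([0, 1]))
        assert len(regions) == 2

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.sets(st.integers(0, 50), min_size=1))
    def test_merged_regions_disjoint_and_cover_all_selected(self, chosen):
        scores = scores_frame(np.ones(51), np.ones(51))
        selected = np.array(sorted(chosen))
        regions = merge_selected(scores, selected)
        assert regions["n_windows"].sum() == len(selected)
        assert len(regions) <= len(selected)
        prev_end = {}
        for row in regions.itertuples(index=False):
            if row.chrom in prev_end:
                assert row.start > prev_end[row.chrom]  # disjoint, not book-ended
            prev_end[row.chrom] = row.end

    def test_empty_selection_gives_empty_frame(self):
        scores = scores_frame([1], [1])
        assert len(merge_selected(scores, np.array([], dtype=int))) == 0


class TestSelectWindows:
    def test_funnel_is_monotone(self, rng):
        y_a = rng.poisson(100, size=2000).astype(float) + 1
        y_b = rng.poisson(100, size=2000).astype(float) + 1
        scores = scores_frame(y_a, y_b)
        selected, eligible, _, bins = select_windows(scores, SelectionParams())
        assert len(selected) <= len(eligible) <= scores["defined"].sum()
        assert len(bins) >= 1
        assert set(selected).issubset(set(eligible))

    def test_both_sides_is_union_of_passes(self, rng):
        y_a = rng.poisson(100, size=2000).astype(float) + 1
        y_b = rng.poisson(100, size=2000).astype(float) + 1
        scores = scores_frame(y_a, y_b)
        lo, *_ = select_windows(scores, SelectionParams(side="lower"))
        hi, *_ = select_windows(scores, SelectionParams(side="upper"))
        both, *_ = select_windows(scores, SelectionParams(side="both"))
        assert set(both) == set(lo) | set(hi)


class TestEvaluateAgainstTruth:
    def region_frame(self, triples):
        return pd.DataFrame(triples, columns=["chrom", "start", "end"])

    def test_perfect_calls(self):
        truth = [("chrI", 100, 200), ("chrI", 500, 700)]
        calls = self.region_frame([("chrI", 120, 180), ("chrI", 450, 550)])
        m = evaluate_against_truth(calls, truth)
        assert m["sensitivity"] == 1.0 and m["precision"] == 1.0
        assert m["false_calls"] == 0

    def test_no_calls_degenerate(self):
        truth = [("chrI", 100, 200)]
        m = evaluate_against_truth(self.region_frame([]), truth)
        assert m["sensitivity"] == 0.0
        assert m["precision"] == 0.0 and not m["precision_defined"]

    def test_min_overlap_threshold(self):
        truth = [("chrI", 100, 200)]
        calls = self.region_frame([("chrI", 195, 300)])
        assert evaluate_against_truth(calls, truth, min_overlap=5)["sensitivity"] == 1.0
        assert evaluate_against_truth(calls, truth, min_overlap=6)["sensitivity"] == 0.0

    def test_matches_per_base_oracle_on_random_instance(self, rng):
        # oracle: per-base sets on a 1000 bp chromosome
        def random_intervals(k):
            out = []
            for _ in range(k):
                s = int(rng.integers(0, 990))
                out.append(("chrI", s, int(rng.integers(s + 1, 1000))))
            return out

        truth = random_intervals(5)
        calls = random_intervals(8)
        m = evaluate_against_truth(self.region_frame(calls), truth)
        call_bases = set()
        for _, s, e in calls:
            call_bases.update(range(s, e))
        hits = [len(set(range(s, e)) & call_bases) >= 1 for _, s, e in truth]
        assert m["sensitivity"] == pytest.approx(np.mean(hits))
        truth_bases = set()
        for _, s, e in truth:
            truth_bases.update(range(s, e))
        prec = np.mean([len(set(range(s, e)) & truth_bases) >= 1 for _, s, e in calls])
        assert m["precision"] == pytest.approx(prec)
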