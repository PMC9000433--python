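"""Greedy coverage selection: hand examples, oracle equivalence, properties."""

import itertools
import json

import numpy as np
import pytest

from strainselect import (
    GroupAssignment,
    Threshold,
    compare_selections,
    percent_captured,
    percent_reduction,
    prioritize_all,
    prioritize_group,
)

from conftest import matrix_from_sets, random_feature_sets


def greedy_oracle(feature_sets: dict[str, set[int]], threshold: float) -> list[str]:
    """Independent brute-force simulation of the selection rule.

    At each step: recount each unselected member's uncovered features
    from scratch, take the maximum (lexicographically smallest id on
    ties), stop as soon as covered/|U| >= threshold (inclusive); members
    with zero uncovered features are never taken.
    """
    universe = set()
    for s in feature_sets.values():
        universe |= s
    if not universe:
        return []
    chosen: list[str] = []
    covered: set[int] = set()
    while len(covered) / len(universe) < threshold:
        best = None
        for iso in sorted(feature_sets):
            if iso in chosen:
                continue
            gain = len(feature_sets[iso] - covered)
            if gain == 0:
                continue
            if best is None or gain > len(feature_sets[best] - covered):
                best = iso
        if best is None:
            break
        chosen.append(best)
        covered |= feature_sets[best]
    return chosen


class TestHandExamples:
    def test_three_member_tie_break(self):
        sets = {"A": {1, 2, 3}, "B": {3, 4}, "C": {5}}
        sel = prioritize_group(set(sets), matrix_from_sets(sets), Threshold(0.75))
        assert sel.universe_size == 5
        assert sel.selected == ["A", "B"]
        assert sel.cumulative_captured == [3, 4]
        assert sel.captured_fraction == pytest.approx(0.8)

    def test_single_member(self):
        sets = {"A": {1, 2}}
        sel = prioritize_group({"A"}, matrix_from_sets(sets), Threshold(0.01))
        assert sel.selected == ["A"]
        assert sel.captured_fraction == 1.0

    def test_redundant_member_never_selected_at_full_threshold(self):
        sets = {"A": {1}, "B": {2}, "C": {1}}
        sel = prioritize_group(set(sets), matrix_from_sets(sets), Threshold(1.0))
        assert sel.selected == ["A", "B"]
        assert sel.captured_fraction == 1.0

    def test_empty_universe_selects_nothing(self):
        sets = {"A": set(), "B": set()}
        fm = matrix_from_sets(sets)
        sel = prioritize_group(set(sets), fm, Threshold(0.75))
        assert sel.selected == [] and sel.captured_fraction == 1.0
        forced = prioritize_group(set(sets), fm, Threshold(0.75), min_per_group=1)
        assert forced.selected == ["A"]

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            prioritize_group(set(), matrix_from_sets({"A": {0}}), Threshold(0.5))

    def test_bad_threshold_rejected(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                Threshold(bad)


class TestOracleEquivalence:
    @pytest.mark.parametrize("threshold", [0.25, 0.5, 0.75, 1.0])
    def test_exhaustive_small_instances(self, threshold):
        # every binary 3-isolate x 3-feature incidence pattern
        ids = ["a", "b", "c"]
        for bits in itertools.product([0, 1], repeat=9):
            sets = {
                ids[i]: {j for j in range(3) if bits[3 * i + j]} for i in range(3)
            }
            if not set().union(*sets.values()):
                continue
            fm = matrix_from_sets(sets)
            labels = sorted(set().union(*sets.values()))
            col_sets = {k: {labels.index(x) for x in v} for k, v in sets.items()}
            sel = prioritize_group(set(sets), fm, Threshold(threshold))
            assert sel.selected == greedy_oracle(col_sets, threshold)

    def test_random_instances_up_to_6x8(self, rng):
        for _ in range(300):
            n_iso = int(rng.integers(2, 7))
            n_feat = int(rng.integers(1, 9))
            thr = float(rng.uniform(0.05, 1.0))
            sets = random_feature_sets(rng, n_iso, n_feat, density=0.4)
            sel = prioritize_group(set(sets), matrix_from_sets(sets), Threshold(thr))
            assert sel.selected == greedy_oracle(sets, thr)


class TestProperties:
    def test_coverage_guarantee_and_minimality(self, rng):
        for _ in range(100):
            n_iso = int(rng.integers(2, 10))
            n_feat = int(rng.integers(1, 20))
            thr = float(rng.uniform(0.1, 1.0))
            sets = random_feature_sets(rng, n_iso, n_feat)
            fm = matrix_from_sets(sets)
            sel = prioritize_group(set(sets), fm, Threshold(thr))
            if sel.universe_size == 0:
                continue
            assert sel.captured_fraction >= thr
            # strictly increasing coverage along the pick sequence
            assert all(
                b > a
                for a, b in zip(sel.cumulative_captured, sel.cumulative_captured[1:])
            )
            # minimality w.r.t. the stopping rule
            if sel.selected:
                without_last = set()
                for iso in sel.selected[:-1]:
                    without_last |= fm.features_of(iso)
                assert len(without_last) / sel.universe_size < thr

    def test_overshoot_is_possible(self):
        # one isolate carries 3 of 4 features; threshold 0.5 overshoots to 0.75
        sets = {"A": {0, 1, 2}, "B": {3}}
        sel = prioritize_group(set(sets), matrix_from_sets(sets), Threshold(0.5))
        assert sel.captured_fraction > 0.5

    def test_threshold_monotonicity(self, rng):
        for _ in range(20):
            n_iso = int(rng.integers(3, 9))
            n_feat = int(rng.integers(4, 16))
            sets = random_feature_sets(rng, n_iso, n_feat)
            fm = matrix_from_sets(sets)
            ga = GroupAssignment(
                group_of={iso: 1 for iso in sets}, n_groups=1, cut_mode="k", cut_value=1
            )
            prev = 0
            for thr in np.arange(0.1, 1.01, 0.1):
                n_sel = prioritize_all(ga, fm, Threshold(float(thr))).n_selected_total
                assert n_sel >= prev
                prev = n_sel

    def test_determinism(self, rng):
        sets = random_feature_sets(rng, 8, 20)
        fm = matrix_from_sets(sets)
        ga = GroupAssignment(
            group_of={iso: 1 + (i % 3) for i, iso in enumerate(sorted(sets))},
            n_groups=3,
            cut_mode="k",
            cut_value=3,
        )
        r1 = prioritize_all(ga, fm, Threshold(0.75)).to_report()
        r2 = prioritize_all(ga, fm, Threshold(0.75)).to_report()
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)


class TestPrioritizeAll:
    def test_singleton_groups_select_everyone(self):
        sets = {f"I{k}": {k} for k in range(5)}
        fm = matrix_from_sets(sets)
        ga = GroupAssignment(
            group_of={iso: i + 1 for i, iso in enumerate(sorted(sets))},
            n_groups=5,
            cut_mode="k",
            cut_value=5,
        )
        lib = prioritize_all(ga, fm, Threshold(0.75))
        assert lib.n_selected_total == 5
        assert lib.n_features_captured == 5

    def test_one_big_group_equals_single_call(self, rng):
        sets = random_feature_sets(rng, 6, 12)
        fm = matrix_from_sets(sets)
        ga = GroupAssignment(
            group_of={iso: 1 for iso in sets}, n_groups=1, cut_mode="k", cut_value=1
        )
        lib = prioritize_all(ga, fm, Threshold(0.75))
        single = prioritize_group(set(sets), fm, Threshold(0.75), group_id=1)
        assert lib.per_group[0].selected == single.selected
        assert lib.n_selected_total == single.n_selected


class TestReportArithmetic:
    @pytest.mark.parametrize(
        "total,selected,expected",
        [(819, 189, 77), (819, 236, 71), (819, 293, 64), (100, 100, 0)],
    )
    def test_percent_reduction(self, total, selected, expected):
        assert percent_reduction(total, selected) == expected

    @pytest.mark.parametrize(
        "captured,total,expected", [(5455, 6624, 82), (0, 10, 0), (10, 10, 100)]
    )
    def test_percent_captured(self, captured, total, expected):
        assert percent_captured(captured, total) == expected

    def test_half_up_rounding(self):
        assert percent_captured(1, 8) == 13  # 12.5 rounds up, not to even
        assert percent_reduction(8, 7) == 13

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0, 0)
        with pytest.raises(ValueError):
            percent_captured(0, 0)


class TestCompareSelections:
    def test_identical_sets(self):
        feats = set(range(100))
        result = compare_selections(
            {"x": (["i1"], feats), "y": (["i2"], feats), "z": (["i3"], feats)}
        )
        venn = result["venn_captured_features"]
        assert venn["all_three"] == 100
        assert sum(v for k, v in venn.items() if k != "all_three") == 0

    def test_disjoint_sets(self):
        result = compare_selections(
            {"x": ([], {1}), "y": ([], {2}), "z": ([], {3})}
        )
        venn = result["venn_captured_features"]
        assert venn["x_only"] == venn["y_only"] == venn["z_only"] == 1
        assert venn["all_three"] == 0

    def test_partial_overlaps(self):
        result = compare_selections(
            {
                "alg": (["i"] * 2, {1, 2, 3}),
                "r1": (["i"] * 3, {2, 3, 4}),
                "r2": (["i"] * 4, {3, 4, 5}),
            }
        )
        venn = result["venn_captured_features"]
        assert venn["all_three"] == 1
        assert venn["alg_r1_only"] == 1
        assert venn["r1_r2_only"] == 1
        assert venn["alg_r2_only"] == 0
        assert venn["alg_only"] == 1 and venn["r1_only"] == 0 and venn["r2_only"] == 1
        assert result["isolate_count_differences"]["r1_minus_alg"] == 1
        assert result["isolate_count_differences"]["r2_minus_alg"] == 2
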