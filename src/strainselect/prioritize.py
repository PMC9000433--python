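"""Greedy per-group isolate selection — the pipeline's core.

Within each pseudo-phylogenetic group the algorithm repeatedly picks the
isolate carrying the most small-molecule mass features not yet covered
by earlier picks (selected isolates and their features are removed from
the group before re-counting), until the selected isolates jointly carry
at least a threshold fraction of the group's distinct features.  Because
features accumulate isolate-by-isolate rather than one at a time, the
final captured fraction can overshoot the threshold; it can never fall
short of it, which is the guarantee that motivates automating the step.

This is greedy maximum coverage with an inclusive coverage stopping
rule, run independently per group; it is not a minimum-cardinality set
cover and makes no cross-group trade-offs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cluster import GroupAssignment
from .features import FeatureMatrix

__all__ = [
    "Threshold",
    "GroupSelection",
    "LibrarySelection",
    "prioritize_group",
    "prioritize_all",
    "percent_reduction",
    "percent_captured",
    "compare_selections",
]


@dataclass(frozen=True)
class Threshold:
    """Minimum fraction of a group's distinct np features to capture."""

    value: float

    def __post_init__(self) -> None:
        if not 0 < self.value <= 1:
            raise ValueError(f"threshold must lie in (0, 1], got {self.value}")


@dataclass
class GroupSelection:
    """Ordered greedy selection for one group.

    ``cumulative_captured[i]`` is the number of distinct features covered
    after the first ``i + 1`` picks; it is strictly increasing because an
    isolate offering no uncovered feature is never picked.
    ``captured_fraction`` is 1.0 by convention for a group with no np
    features at all.
    """

    group_id: int
    universe_size: int
    selected: list[str]
    cumulative_captured: list[int]
    captured_fraction: float
    captured_features: set[int] = field(default_factory=set)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


@dataclass
class LibrarySelection:
    """Collection-level result: per-group selections plus totals."""

    per_group: list[GroupSelection]
    n_isolates_total: int
    n_selected_total: int
    n_features_total: int
    n_features_captured: int
    threshold: Threshold

    @property
    def selected_isolates(self) -> list[str]:
        return [iso for gs in self.per_group for iso in gs.selected]

    def to_report(self) -> dict:
        """JSON-serializable selection report."""
        return {
            "threshold": self.threshold.value,
            "collection": {
                "n_isolates_total": self.n_isolates_total,
                "n_selected_total": self.n_selected_total,
                "n_features_total": self.n_features_total,
                "n_features_captured": self.n_features_captured,
                "percent_reduction": percent_reduction(
                    self.n_isolates_total, self.n_selected_total
                ),
                "percent_captured": (
                    percent_captured(self.n_features_captured, self.n_features_total)
                    if self.n_features_total
                    else 100
                ),
            },
            "groups": [
                {
                    "group_id": gs.group_id,
                    "universe_size": gs.universe_size,
                    "selected": list(gs.selected),
                    "cumulative_captured": list(gs.cumulative_captured),
                    "captured_fraction": gs.captured_fraction,
                    "captured_feature_ids": sorted(gs.captured_features),
                }
                for gs in self.per_group
            ],
        }


def prioritize_group(
    members: Iterable[str],
    np_matrix: FeatureMatrix,
    threshold: Threshold,
    group_id: int = 0,
    min_per_group: int = 0,
) -> GroupSelection:
    """Greedily select isolates of one group until coverage >= threshold.

    At each step the unselected member with the most uncovered features
    is picked (ties broken by lexicographically smallest isolate id);
    its features are marked covered and the loop stops as soon as
    covered / universe >= threshold.  Members offering zero uncovered
    features are never selected.  A group with an empty feature universe
    selects nothing (captured_fraction 1.0 by convention) unless
    ``min_per_group=1`` forces one representative.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("group has no members")
    missing = [m for m in members if m not in np_matrix.isolate_ids]
    if missing:
        raise ValueError(f"isolate(s) not in feature matrix: {missing}")

    feats: dict[str, set[int]] = {m: np_matrix.features_of(m) for m in members}
    universe: set[int] = set().union(*feats.values()) if feats else set()

    selected: list[str] = []
    cumulative: list[int] = []
    covered: set[int] = set()
    if universe:
        while len(covered) / len(universe) < threshold.value:
            best_iso, best_gain = None, 0
            for iso in members:  # members sorted: first max is the lexicographic tie-winner
                if iso in selected:
                    continue
                gain = len(feats[iso] - covered)
                if gain > best_gain:
                    best_iso, best_gain = iso, gain
            if best_iso is None:  # unreachable while coverage < 1 <= threshold
                break
            selected.append(best_iso)
            covered |= feats[best_iso]
            cumulative.append(len(covered))
    if min_per_group and not selected:
        # forced representative of a featureless group: captures nothing
        selected.append(members[0])
    fraction = len(covered) / len(universe) if universe else 1.0
    return GroupSelection(
        group_id=group_id,
        universe_size=len(universe),
        selected=selected,
        cumulative_captured=cumulative,
        captured_fraction=fraction,
        captured_features=covered,
    )


def prioritize_all(
    assignment: GroupAssignment,
    np_matrix: FeatureMatrix,
    threshold: Threshold,
    min_per_group: int = 0,
) -> LibrarySelection:
    """Run the greedy selection over every group, ascending group id."""
    per_group = [
        prioritize_group(
            assignment.members(g), np_matrix, threshold, group_id=g,
            min_per_group=min_per_group,
        )
        for g in range(1, assignment.n_groups + 1)
    ]
    captured_union: set[int] = set()
    for gs in per_group:
        captured_union |= gs.captured_features
    return LibrarySelection(
        per_group=per_group,
        n_isolates_total=len(assignment.group_of),
        n_selected_total=sum(gs.n_selected for gs in per_group),
        n_features_total=np_matrix.n_features,
        n_features_captured=len(captured_union),
        threshold=threshold,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percent_reduction(n_total: int, n_selected: int) -> int:
    """Percent of isolates removed from the collection, rounded half-up."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_selected <= n_total:
        raise ValueError("n_selected must lie in [0, n_total]")
    return _round_half_up(100.0 * (n_total - n_selected) / n_total)


def percent_captured(n_captured: int, n_features_total: int) -> int:
    """Percent of distinct features covered by the library, rounded half-up."""
    if n_features_total <= 0:
        raise ValueError("n_features_total must be positive")
    if not 0 <= n_captured <= n_features_total:
        raise ValueError("n_captured must lie in [0, n_features_total]")
    return _round_half_up(100.0 * n_captured / n_features_total)


def compare_selections(
    selections: Mapping[str, tuple[Sequence[str], set[int]]],
) -> dict:
    """Three-way comparison of libraries by captured features.

    ``selections`` maps a label to (selected isolate ids, captured
    feature-id set), all drawn from one collection-wide feature space.
    Returns the 7 Venn region counts over captured features plus
    per-selection isolate counts and pairwise isolate-count differences.
    """
    if len(selections) != 3:
        raise ValueError("compare_selections expects exactly 3 selections")
    (la, (ia, fa)), (lb, (ib, fb)), (lc, (ic, fc)) = selections.items()
    regions = {
        f"{la}_only": len(fa - fb - fc),
        f"{lb}_only": len(fb - fa - fc),
        f"{lc}_only": len(fc - fa - fb),
        f"{la}_{lb}_only": len((fa & fb) - fc),
        f"{la}_{lc}_only": len((fa & fc) - fb),
        f"{lb}_{lc}_only": len((fb & fc) - fa),
        "all_three": len(fa & fb & fc),
    }
    counts = {la: len(ia), lb: len(ib), lc: len(ic)}
    diffs = {
        f"{x}_minus_{y}": counts[x] - counts[y]
        for x in counts
        for y in counts
        if x != y
    }
    return {
        "venn_captured_features": regions,
        "n_isolates": counts,
        "isolate_count_differences": diffs,
    }
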