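"""Metabolite association networks (MANs).

A MAN is the bipartite graph linking the isolates of one
pseudo-phylogenetic group to the small-molecule m/z features they carry.
Features are binned once, collection-wide, and then restricted per
group, so feature ids are comparable across groups; an isolate with no
small-molecule features still appears as an isolated node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

from .features import FeatureMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .prioritize import GroupSelection

__all__ = ["MAN", "build_man", "annotate_man"]


@dataclass
class MAN:
    """Bipartite isolate-feature network for one group.

    ``selected`` / ``captured`` are annotation maps filled in by
    :func:`annotate_man`; empty until a selection is applied.
    """

    group_id: int
    isolate_nodes: set[str]
    feature_nodes: set[int]
    edges: set[tuple[str, int]]
    selected: dict[str, bool] = field(default_factory=dict)
    captured: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iso, feat in self.edges:
            if iso not in self.isolate_nodes or feat not in self.feature_nodes:
                raise ValueError(f"edge ({iso!r}, {feat}) references unknown node")
        touched = {f for _, f in self.edges}
        if touched != self.feature_nodes:
            raise ValueError("every feature node must be incident to >= 1 edge")

    def neighbors(self, isolate_id: str) -> set[int]:
        return {f for i, f in self.edges if i == isolate_id}

    @property
    def n_isolates(self) -> int:
        return len(self.isolate_nodes)

    @property
    def n_features(self) -> int:
        return len(self.feature_nodes)


def build_man(
    group_members: Iterable[str], np_matrix: FeatureMatrix, group_id: int
) -> MAN:
    """Build the MAN of one group from the collection-wide np feature matrix."""
    members = set(group_members)
    unknown = members - set(np_matrix.isolate_ids)
    if unknown:
        raise ValueError(f"unknown isolate(s) in group {group_id}: {sorted(unknown)}")
    edges: set[tuple[str, int]] = set()
    for iso in members:
        for feat in np_matrix.features_of(iso):
            edges.add((iso, feat))
    return MAN(
        group_id=group_id,
        isolate_nodes=members,
        feature_nodes={f for _, f in edges},
        edges=edges,
    )


def annotate_man(man: MAN, selection: "GroupSelection") -> MAN:
    """Flag selected isolates and captured features on a MAN (in place).

    A feature is captured iff it is adjacent to at least one selected
    isolate; the remainder are the features the library misses.
    """
    if selection.group_id != man.group_id:
        raise ValueError(
            f"selection is for group {selection.group_id}, MAN is group {man.group_id}"
        )
    chosen = set(selection.selected)
    stray = chosen - man.isolate_nodes
    if stray:
        raise ValueError(f"selection contains non-member isolate(s): {sorted(stray)}")
    man.selected = {iso: iso in chosen for iso in man.isolate_nodes}
    captured_feats: set[int] = set()
    for iso, feat in man.edges:
        if iso in chosen:
            captured_feats.add(feat)
    man.captured = {f: f in captured_feats for f in man.feature_nodes}
    return man
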