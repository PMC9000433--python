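"""Protein-fingerprint hierarchical clustering and dendrogram cuts.

Isolates are compared on their binary protein-region feature rows
(cosine distance by default, UPGMA linkage by default) and grouped into
pseudo-phylogenetic groups by cutting the resulting dendrogram either
at a height or into a requested number of groups k.  The cut itself is
a user decision — no automatic cut-height selection is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .features import FeatureMatrix

__all__ = [
    "Dendrogram",
    "GroupAssignment",
    "distance_matrix",
    "build_dendrogram",
    "cut_dendrogram",
]

_METRICS = ("cosine", "jaccard", "dice")
_LINKAGES = ("average", "ward", "complete")


@dataclass
class Dendrogram:
    """Agglomerative clustering result over a set of isolates.

    ``linkage_matrix`` is in scipy's standard (n-1, 4) encoding: each row
    merges two nodes (leaves are 0..n-1, internal nodes n..2n-2 in merge
    order) at a given height.
    """

    leaves: list[str]
    linkage_matrix: np.ndarray
    linkage_method: str
    distance_metric: str

    def __post_init__(self) -> None:
        self.linkage_matrix = np.asarray(self.linkage_matrix, dtype=float)
        n = len(self.leaves)
        if self.linkage_matrix.shape != (max(n - 1, 0), 4):
            raise ValueError("linkage matrix must have n_leaves - 1 rows")
        heights = self.linkage_matrix[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix
        ]


@dataclass
class GroupAssignment:
    """Partition of isolates into pseudo-phylogenetic groups (1..G)."""

    group_of: dict[str, int]
    n_groups: int
    cut_mode: str
    cut_value: float

    def __post_init__(self) -> None:
        groups = set(self.group_of.values())
        if groups != set(range(1, self.n_groups + 1)):
            raise ValueError("group labels must be exactly 1..n_groups, all nonempty")

    def members(self, group_id: int) -> set[str]:
        return {iso for iso, g in self.group_of.items() if g == group_id}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"isolate_id": list(self.group_of), "group": list(self.group_of.values())}
        )

    def write_table(self, path: Union[str, Path], delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)

    @classmethod
    def read_table(
        cls, path: Union[str, Path], delimiter: str = "\t"
    ) -> "GroupAssignment":
        df = pd.read_csv(path, sep=delimiter)
        group_of = {
            str(iso): int(g) for iso, g in zip(df["isolate_id"], df["group"])
        }
        return cls(
            group_of=group_of,
            n_groups=max(group_of.values()),
            cut_mode="file",
            cut_value=0.0,
        )


def distance_matrix(matrix: FeatureMatrix, metric: str = "cosine") -> np.ndarray:
    """Pairwise distances between binary incidence rows.

    cosine: 1 - a.b/(|a||b|); jaccard: 1 - |intersection|/|union|;
    dice: 1 - 2|intersection|/(|a|+|b|).  An all-zero row is defined to
    be at distance 1 from every other isolate and 0 from itself.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    x = matrix.incidence.astype(float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("distance_matrix requires at least 2 isolates")
    inter = x @ x.T
    sizes = x.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "cosine":
            denom = np.sqrt(np.outer(sizes, sizes))
            sim = np.where(denom > 0, inter / denom, 0.0)
        elif metric == "jaccard":
            union = sizes[:, None] + sizes[None, :] - inter
            sim = np.where(union > 0, inter / union, 0.0)
        else:  # dice
            denom = sizes[:, None] + sizes[None, :]
            sim = np.where(denom > 0, 2 * inter / denom, 0.0)
    dist = 1.0 - sim
    empty = sizes == 0
    dist[empty, :] = 1.0
    dist[:, empty] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    return (dist + dist.T) / 2.0


def build_dendrogram(
    dist: np.ndarray,
    matrix_or_labels,
    linkage: str = "average",
    metric: str = "cosine",
) -> Dendrogram:
    """Hierarchically cluster a symmetric distance matrix.

    ``matrix_or_labels`` supplies leaf labels (a FeatureMatrix or a list
    of isolate ids).  The agglomeration is scipy's, deterministic for a
    fixed input.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    labels = (
        list(matrix_or_labels.isolate_ids)
        if isinstance(matrix_or_labels, FeatureMatrix)
        else list(matrix_or_labels)
    )
    dist = np.asarray(dist, dtype=float)
    if np.any(np.isnan(dist)):
        raise ValueError("distance matrix contains NaN")
    if dist.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape does not match label count")
    if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    z = _scipy_linkage(squareform(dist, checks=False), method=linkage)
    return Dendrogram(
        leaves=labels,
        linkage_matrix=z,
        linkage_method=linkage,
        distance_metric=metric,
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def cut_dendrogram(
    dendrogram: Dendrogram, mode: str, value: Union[int, float]
) -> GroupAssignment:
    """Cut a dendrogram into groups.

    mode="height": groups are the connected subtrees whose internal
    merge heights are all <= value.  mode="k": exactly k groups, formed
    by applying the first n - k merges (i.e. removing the k - 1 highest,
    ties resolved by merge order).  Groups are numbered 1..G in order of
    their first leaf.
    """
    n = dendrogram.n_leaves
    z = dendrogram.linkage_matrix
    if mode == "k":
        k = int(value)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        n_merges = n - k
    elif mode == "height":
        if value < 0:
            raise ValueError("cut height must be >= 0")
        n_merges = int(np.sum(z[:, 2] <= value)) if n > 1 else 0
    else:
        raise ValueError(f"mode must be 'height' or 'k', got {mode!r}")

    uf = _UnionFind(2 * n - 1 if n > 1 else 1)
    for row in range(n_merges):
        a, b = int(z[row, 0]), int(z[row, 1])
        uf.union(a, n + row)
        uf.union(b, n + row)

    # label groups 1..G in leaf order
    label_of_root: dict[int, int] = {}
    group_of: dict[str, int] = {}
    for leaf, iso in enumerate(dendrogram.leaves):
        root = uf.find(leaf)
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root) + 1
        group_of[iso] = label_of_root[root]
    return GroupAssignment(
        group_of=group_of,
        n_groups=len(label_of_root),
        cut_mode=mode,
        cut_value=float(value),
    )
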