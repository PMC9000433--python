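"""Cross-isolate feature binning.

Consensus peaks from all isolates are pooled per mass region and split
into shared m/z features by one-dimensional single-linkage clustering:
a new bin starts wherever the gap between consecutive pooled m/z values
exceeds the matching tolerance.  This is deterministic and independent
of isolate or peak order, and avoids the phase artifacts of fixed-width
grid binning.  The result is a binary isolate x feature incidence
matrix; intensities are not used downstream, only presence/absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .types import ConsensusPeakList

__all__ = ["FeatureBin", "FeatureMatrix", "bin_features", "feature_counts"]


@dataclass(frozen=True)
class FeatureBin:
    """One cross-isolate m/z bin."""

    feature_id: int
    mz_center: float
    mz_min: float
    mz_max: float
    region: str

    def __post_init__(self) -> None:
        if not self.mz_min <= self.mz_center <= self.mz_max:
            raise ValueError("bin center must lie within [mz_min, mz_max]")


@dataclass
class FeatureMatrix:
    """Binary isolate x binned-feature incidence matrix for one region."""

    isolate_ids: list[str]
    bins: list[FeatureBin]
    incidence: np.ndarray  # shape (n_isolates, n_bins), dtype int8
    region: str

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.int8)
        if self.incidence.shape != (len(self.isolate_ids), len(self.bins)):
            raise ValueError("incidence shape does not match ids/bins")
        if self.bins and np.any(self.incidence.sum(axis=0) == 0):
            raise ValueError("feature matrix contains an empty bin column")

    @property
    def n_isolates(self) -> int:
        return len(self.isolate_ids)

    @property
    def n_features(self) -> int:
        return len(self.bins)

    def row(self, isolate_id: str) -> np.ndarray:
        return self.incidence[self.isolate_ids.index(isolate_id)]

    def features_of(self, isolate_id: str) -> set[int]:
        """Feature ids carried by one isolate."""
        return set(np.flatnonzero(self.row(isolate_id)).tolist())

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{b.mz_center:.6g}" for b in self.bins]
        return pd.DataFrame(self.incidence, index=self.isolate_ids, columns=cols)

    def write_table(self, path: Union[str, Path], delimiter: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=delimiter, index_label="isolate_id")


def bin_features(
    consensus_lists: Sequence[ConsensusPeakList], tol: float
) -> FeatureMatrix:
    """Bin consensus peaks of all isolates into shared features.

    All lists must carry the same region tag.  Pooled m/z values are
    sorted and split wherever a consecutive gap exceeds ``tol``; each
    resulting cluster is one feature.  A bin may contain several peaks
    from one isolate (still a single incidence entry).
    """
    if not consensus_lists:
        raise ValueError("bin_features requires at least one consensus list")
    if tol <= 0:
        raise ValueError("tol must be positive")
    regions = {c.region for c in consensus_lists}
    if len(regions) != 1 or None in regions:
        raise ValueError(f"consensus lists mix regions: {sorted(map(str, regions))}")
    (region,) = regions
    ids = [c.isolate_id for c in consensus_lists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate isolate ids in consensus lists")

    mzs, owner = [], []
    for i, c in enumerate(consensus_lists):
        for p in c.peaks:
            mzs.append(p.mz)
            owner.append(i)
    mz_arr = np.asarray(mzs, dtype=float)
    owner_arr = np.asarray(owner)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, owner_arr = mz_arr[order], owner_arr[order]

    bins: list[FeatureBin] = []
    incidence = np.zeros((len(ids), 0), dtype=np.int8)
    if mz_arr.size:
        breaks = np.flatnonzero(np.diff(mz_arr) > tol) + 1
        clusters = np.split(np.arange(mz_arr.size), breaks)
        incidence = np.zeros((len(ids), len(clusters)), dtype=np.int8)
        for j, idx in enumerate(clusters):
            member_mz = mz_arr[idx]
            # clamp: float rounding of the mean may overshoot by one ulp
            center = min(max(float(member_mz.mean()), float(member_mz.min())),
                         float(member_mz.max()))
            bins.append(
                FeatureBin(
                    feature_id=j,
                    mz_center=center,
                    mz_min=float(member_mz.min()),
                    mz_max=float(member_mz.max()),
                    region=region,
                )
            )
            incidence[owner_arr[idx], j] = 1
    return FeatureMatrix(isolate_ids=ids, bins=bins, incidence=incidence, region=region)


def read_feature_table(
    path: Union[str, Path], region: str, delimiter: str = "\t"
) -> FeatureMatrix:
    """Read a feature matrix written by :meth:`FeatureMatrix.write_table`.

    Bin extents are not stored in the table, so reconstructed bins carry
    ``mz_min == mz_center == mz_max``; sufficient for stage handoff
    (grouping, networks, prioritization), which only uses centers.
    """
    df = pd.read_csv(path, sep=delimiter, index_col="isolate_id")
    bins = [
        FeatureBin(
            feature_id=j,
            mz_center=float(col),
            mz_min=float(col),
            mz_max=float(col),
            region=region,
        )
        for j, col in enumerate(df.columns)
    ]
    return FeatureMatrix(
        isolate_ids=[str(i) for i in df.index],
        bins=bins,
        incidence=df.to_numpy(dtype=np.int8),
        region=region,
    )


def feature_counts(matrix: FeatureMatrix) -> pd.Series:
    """Number of features carried by each isolate (incidence row sums)."""
    return pd.Series(
        matrix.incidence.sum(axis=1), index=matrix.isolate_ids, name="n_features"
    )
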