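"""Replicate consensus, optional peak picking, blank subtraction, region split.

Each isolate is measured in technical replicates (triplicates by
convention).  A peak is retained only if it appears, within a matching
tolerance, in at least a ``min_presence`` fraction of replicates —
replicate-private peaks (shot noise, matrix clusters) are discarded.
The surviving consensus list is then split into the protein fingerprint
region (2000–15000 Da) and the small-molecule region (200–2000 Da).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, median_filter

from .types import (
    NP_REGION,
    PROTEIN_REGION,
    ConsensusPeakList,
    Peak,
    PeakList,
)

logger = logging.getLogger(__name__)

__all__ = ["pick_peaks", "merge_replicates", "subtract_blank", "split_regions"]

#: Rolling-median window (points) used for baseline estimation.
BASELINE_WINDOW = 101


def pick_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    snr_min: float = 4.0,
    halfwindow: int = 10,
    isolate_id: str = "unknown",
    replicate_id: str = "1",
) -> PeakList:
    """Pick centroid peaks from a profile-mode spectrum.

    A point is a peak if it is the intensity maximum within +/-
    ``halfwindow`` points and its baseline-subtracted intensity exceeds
    ``snr_min`` times the noise level.  The baseline is a rolling median
    (window 101 points); the noise is the median absolute deviation of
    the baseline-subtracted intensity scaled by 1.4826 (the consistency
    factor for Gaussian noise).
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity arrays must have equal length")
    if mz.size < 3:
        raise ValueError("profile spectrum needs at least 3 points")
    if np.any(np.diff(mz) <= 0):
        raise ValueError("profile mz values must be strictly increasing")

    baseline = median_filter(intensity, size=BASELINE_WINDOW, mode="nearest")
    resid = intensity - baseline
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))

    size = 2 * halfwindow + 1
    is_local_max = intensity >= maximum_filter1d(intensity, size=size, mode="nearest")
    if noise > 0:
        snr = resid / noise
    else:  # noiseless signal: any positive residual is infinitely significant
        snr = np.where(resid > 0, np.inf, 0.0)
    candidates = np.flatnonzero(is_local_max & (snr >= snr_min) & (resid > 0))

    # collapse plateaus / windows sharing one apex: keep the highest point
    # of each run of candidates closer than halfwindow samples apart
    peaks: list[Peak] = []
    i = 0
    while i < len(candidates):
        j = i
        while j + 1 < len(candidates) and candidates[j + 1] - candidates[j] <= halfwindow:
            j += 1
        run = candidates[i : j + 1]
        apex = run[np.argmax(intensity[run])]
        peaks.append(
            Peak(
                mz=float(mz[apex]),
                intensity=float(intensity[apex]),
                snr=float(snr[apex]) if np.isfinite(snr[apex]) else None,
            )
        )
        i = j + 1
    return PeakList(isolate_id=isolate_id, replicate_id=replicate_id, peaks=peaks)


def _gap_clusters(values: np.ndarray, tol: float) -> list[np.ndarray]:
    """Split sorted 1-D values into single-linkage clusters at gaps > tol."""
    if values.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(values) > tol) + 1
    return np.split(np.arange(values.size), breaks)


def merge_replicates(
    replicates: Sequence[PeakList],
    tol: float,
    min_presence: float = 2 / 3,
) -> ConsensusPeakList:
    """Build one consensus peak list from an isolate's technical replicates.

    Peaks from all replicates are pooled and grouped by single-linkage
    clustering of m/z values (cluster break where the gap between
    consecutive m/z values exceeds ``tol``).  Each cluster becomes one
    consensus peak with intensity-weighted mean m/z, mean intensity, and
    presence = distinct contributing replicates / number of replicates;
    clusters below ``min_presence`` are dropped.
    """
    if not replicates:
        raise ValueError("merge_replicates requires at least one replicate")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must lie in (0, 1]")
    isolate_ids = {r.isolate_id for r in replicates}
    if len(isolate_ids) != 1:
        raise ValueError(f"replicates mix isolate ids: {sorted(isolate_ids)}")
    (isolate_id,) = isolate_ids
    n_rep = len(replicates)

    mzs, intens, rep_idx = [], [], []
    for k, rep in enumerate(replicates):
        for p in rep.peaks:
            mzs.append(p.mz)
            intens.append(p.intensity)
            rep_idx.append(k)
    order = np.argsort(mzs, kind="stable")
    mz_arr = np.asarray(mzs, dtype=float)[order]
    int_arr = np.asarray(intens, dtype=float)[order]
    rep_arr = np.asarray(rep_idx)[order]

    peaks: list[Peak] = []
    presence: list[float] = []
    for idx in _gap_clusters(mz_arr, tol):
        pres = len(set(rep_arr[idx].tolist())) / n_rep
        if pres < min_presence:
            continue
        w = int_arr[idx]
        if w.sum() > 0:
            center = float(np.average(mz_arr[idx], weights=w))
        else:
            center = float(np.mean(mz_arr[idx]))
        peaks.append(Peak(mz=center, intensity=float(np.mean(w))))
        presence.append(pres)
    return ConsensusPeakList(
        isolate_id=isolate_id, peaks=peaks, presence=presence, n_replicates=n_rep
    )


def subtract_blank(
    consensus: ConsensusPeakList, blank: ConsensusPeakList, tol: float
) -> ConsensusPeakList:
    """Remove consensus peaks within ``tol`` Da of any matrix-blank peak."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    blank_mz = np.asarray(blank.mz, dtype=float)
    if blank_mz.size == 0:
        return consensus
    keep_peaks, keep_presence = [], []
    for p, pres in zip(consensus.peaks, consensus.presence):
        if float(np.min(np.abs(blank_mz - p.mz))) > tol:
            keep_peaks.append(p)
            keep_presence.append(pres)
    return ConsensusPeakList(
        isolate_id=consensus.isolate_id,
        peaks=keep_peaks,
        presence=keep_presence,
        n_replicates=consensus.n_replicates,
        region=consensus.region,
    )


def split_regions(
    consensus: ConsensusPeakList,
) -> tuple[ConsensusPeakList, ConsensusPeakList]:
    """Split a consensus list into (protein, np) region lists.

    Peaks outside [200, 15000] Da are dropped with a logged count.  The
    2000.0 Da boundary belongs to the protein region only.
    """
    buckets = {"protein": ([], []), "np": ([], [])}
    dropped = 0
    for p, pres in zip(consensus.peaks, consensus.presence):
        if NP_REGION.contains(p.mz):
            buckets["np"][0].append(p)
            buckets["np"][1].append(pres)
        elif PROTEIN_REGION.contains(p.mz):
            buckets["protein"][0].append(p)
            buckets["protein"][1].append(pres)
        else:
            dropped += 1
    if dropped:
        logger.info(
            "isolate %s: dropped %d peaks outside [200, 15000] Da",
            consensus.isolate_id,
            dropped,
        )
    out = {}
    for name, (pk, pr) in buckets.items():
        out[name] = ConsensusPeakList(
            isolate_id=consensus.isolate_id,
            peaks=pk,
            presence=pr,
            n_replicates=consensus.n_replicates,
            region=name,
        )
    return out["protein"], out["np"]
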