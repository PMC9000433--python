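"""Seeded generator of synthetic isolate collections with planted groups.

The generator emulates the structure the pipeline assumes: isolates fall
into taxonomic groups whose members share most protein-region peaks
(high within-group presence, low cross-group presence) and carry a
group-core set of small-molecule features plus isolate-private accessory
features.  Each technical replicate observes each true peak with some
dropout probability, adds Gaussian m/z jitter, and sprinkles
replicate-private noise peaks — which is precisely what the 2-of-3
replicate consensus rule is designed to remove.

Feature m/z positions are drawn with a minimum pairwise separation of
five times the matching tolerance, so tolerance binning is unambiguous
in noise-free settings; noisy settings relax that deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .types import NP_REGION, PROTEIN_REGION, Peak, PeakList

__all__ = ["SynthParams", "SynthTruth", "simulate_collection"]

#: matching tolerances the separation rule is anchored to (Da)
_TOL_PROTEIN = 2.0
_TOL_NP = 0.2


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the planted-group collection generator."""

    n_groups: int = 5
    isolates_per_group: Union[int, tuple[int, int]] = 8
    n_replicates: int = 3
    protein_pool_per_group: int = 30
    protein_within_presence: float = 0.9
    protein_cross_presence: float = 0.05
    np_core_per_group: int = 10
    np_accessory_per_isolate: int = 5
    replicate_dropout: float = 0.1
    mz_jitter_sd_protein: float = 0.3
    mz_jitter_sd_np: float = 0.03
    noise_peaks_per_replicate: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "protein_pool_per_group",
            "np_core_per_group",
            "np_accessory_per_isolate",
            "noise_peaks_per_replicate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "protein_within_presence",
            "protein_cross_presence",
            "replicate_dropout",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        ipg = self.isolates_per_group
        if isinstance(ipg, int):
            if ipg < 1:
                raise ValueError("isolates_per_group must be >= 1")
        else:
            lo, hi = ipg
            if not 1 <= lo <= hi:
                raise ValueError("isolates_per_group range must satisfy 1 <= lo <= hi")


@dataclass
class SynthTruth:
    """Planted ground truth of a simulated collection."""

    group_of: dict[str, int]
    protein_mz: dict[str, list[float]]  # true protein peak positions per isolate
    np_mz: dict[str, list[float]]  # true np peak positions per isolate
    np_universe_mz: dict[int, list[float]]  # per-group union of true np positions

    def to_dict(self) -> dict:
        return {
            "group_of": self.group_of,
            "protein_mz": self.protein_mz,
            "np_mz": self.np_mz,
            "np_universe_mz": {str(g): v for g, v in self.np_universe_mz.items()},
        }


def _spaced_positions(
    rng: np.random.Generator, n: int, low: float, high: float, min_sep: float
) -> np.ndarray:
    """Draw n positions uniformly in [low, high) with pairwise gaps >= min_sep."""
    if n == 0:
        return np.empty(0)
    if n * min_sep > (high - low):
        raise ValueError(
            f"cannot place {n} features with separation {min_sep} in "
            f"[{low}, {high})"
        )
    accepted: list[float] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError("feature placement failed; region too crowded")
        x = float(rng.uniform(low, high))
        if all(abs(x - a) >= min_sep for a in accepted):
            accepted.append(x)
    return np.sort(np.asarray(accepted))


def simulate_collection(
    params: SynthParams,
) -> tuple[dict[str, dict[str, PeakList]], SynthTruth]:
    """Simulate per-isolate, per-replicate peak lists with known truth.

    Returns ``(peaklists, truth)`` where ``peaklists[isolate][replicate]``
    is a :class:`PeakList` and ``truth`` records the planted partition
    and every isolate's true peak positions.  Fully reproducible from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)

    # group sizes and isolate ids
    if isinstance(params.isolates_per_group, int):
        sizes = [params.isolates_per_group] * params.n_groups
    else:
        lo, hi = params.isolates_per_group
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(params.n_groups)]
    group_of: dict[str, int] = {}
    for g, size in enumerate(sizes, start=1):
        for i in range(size):
            group_of[f"G{g:02d}I{i:02d}"] = g
    isolates = sorted(group_of)
    n_isolates = len(isolates)

    # planted feature positions, collection-wide, with enforced separation
    n_protein = params.n_groups * params.protein_pool_per_group
    n_np = (
        params.n_groups * params.np_core_per_group
        + n_isolates * params.np_accessory_per_isolate
    )
    protein_pos = _spaced_positions(
        rng, n_protein, PROTEIN_REGION.low, PROTEIN_REGION.high, 5 * _TOL_PROTEIN
    )
    np_pos = _spaced_positions(
        rng, n_np, NP_REGION.low, NP_REGION.high, 5 * _TOL_NP
    )
    protein_pool = {
        g: protein_pos[
            (g - 1) * params.protein_pool_per_group : g * params.protein_pool_per_group
        ]
        for g in range(1, params.n_groups + 1)
    }
    np_core = {
        g: np_pos[(g - 1) * params.np_core_per_group : g * params.np_core_per_group]
        for g in range(1, params.n_groups + 1)
    }
    acc_start = params.n_groups * params.np_core_per_group
    np_accessory = {
        iso: np_pos[
            acc_start
            + k * params.np_accessory_per_isolate : acc_start
            + (k + 1) * params.np_accessory_per_isolate
        ]
        for k, iso in enumerate(isolates)
    }

    # true per-isolate peak sets
    protein_mz: dict[str, list[float]] = {}
    np_mz: dict[str, list[float]] = {}
    for iso in isolates:
        g = group_of[iso]
        own: list[float] = []
        for gg in range(1, params.n_groups + 1):
            p = (
                params.protein_within_presence
                if gg == g
                else params.protein_cross_presence
            )
            keep = rng.random(len(protein_pool[gg])) < p
            own.extend(float(x) for x in protein_pool[gg][keep])
        protein_mz[iso] = sorted(own)
        np_mz[iso] = sorted(
            [float(x) for x in np_core[g]] + [float(x) for x in np_accessory[iso]]
        )

    np_universe_mz = {
        g: sorted({x for iso in isolates if group_of[iso] == g for x in np_mz[iso]})
        for g in range(1, params.n_groups + 1)
    }

    # noisy replicate observations
    peaklists: dict[str, dict[str, PeakList]] = {}
    for iso in isolates:
        peaklists[iso] = {}
        for r in range(1, params.n_replicates + 1):
            obs: list[Peak] = []
            for true_mz, jitter_sd, region in (
                (protein_mz[iso], params.mz_jitter_sd_protein, PROTEIN_REGION),
                (np_mz[iso], params.mz_jitter_sd_np, NP_REGION),
            ):
                for x in true_mz:
                    if rng.random() < params.replicate_dropout:
                        continue
                    mz = x + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
                    mz = min(max(mz, region.low), region.high - 1e-9)
                    obs.append(Peak(mz=mz, intensity=float(rng.uniform(20.0, 200.0))))
            # replicate-private noise peaks, uniform over the measured range
            for _ in range(params.noise_peaks_per_replicate):
                obs.append(
                    Peak(
                        mz=float(rng.uniform(NP_REGION.low, PROTEIN_REGION.high)),
                        intensity=float(rng.uniform(5.0, 50.0)),
                    )
                )
            # enforce strictly ascending mz (duplicates vanishingly unlikely)
            obs.sort(key=lambda p: p.mz)
            dedup: list[Peak] = []
            for p in obs:
                if dedup and p.mz <= dedup[-1].mz:
                    continue
                dedup.append(p)
            rep_id = f"r{r}"
            peaklists[iso][rep_id] = PeakList(
                isolate_id=iso, replicate_id=rep_id, peaks=dedup
            )

    truth = SynthTruth(
        group_of=group_of,
        protein_mz=protein_mz,
        np_mz=np_mz,
        np_universe_mz=np_universe_mz,
    )
    return peaklists, truth
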