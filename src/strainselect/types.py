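"""Core domain types shared across the pipeline.

The pipeline's unit of raw input is a :class:`PeakList`: one centroided
MALDI-TOF acquisition for one isolate and one technical replicate.  After
replicate consensus a :class:`ConsensusPeakList` holds the peaks that were
reproducibly observed for an isolate, tagged with the mass region they fall
in (small proteins, 2–15 kDa, used for taxonomic grouping; small molecules,
200–2000 Da, used for natural-product coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "Peak",
    "PeakList",
    "ConsensusPeakList",
    "MassRegion",
    "PROTEIN_REGION",
    "NP_REGION",
    "REGIONS",
]


@dataclass(frozen=True)
class Peak:
    """A single centroided m/z observation.

    Parameters
    ----------
    mz
        Mass-to-charge ratio in Daltons; must be positive.
    intensity
        Peak intensity in arbitrary units; must be non-negative.
    snr
        Signal-to-noise ratio, if known.  Pre-picked peak lists exported
        from vendor software usually lack it.
    """

    mz: float
    intensity: float
    snr: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")
        if self.snr is not None and self.snr < 0:
            raise ValueError(f"peak snr must be non-negative, got {self.snr}")


@dataclass
class PeakList:
    """Centroided peaks for one isolate / technical replicate.

    Peaks are kept strictly ascending in m/z; duplicate m/z values within
    one replicate are forbidden (readers collapse them before construction).
    """

    isolate_id: str
    replicate_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.isolate_id:
            raise ValueError("isolate_id must be nonempty")
        mzs = [p.mz for p in self.peaks]
        for a, b in zip(mzs, mzs[1:]):
            if not a < b:
                raise ValueError(
                    f"peaks must be strictly ascending in mz; got {a} before {b} "
                    f"(isolate {self.isolate_id!r}, replicate {self.replicate_id!r})"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def mz(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensity(self) -> list[float]:
        return [p.intensity for p in self.peaks]


@dataclass(frozen=True)
class MassRegion:
    """A named m/z window.

    ``contains`` uses a half-open upper bound for the small-molecule (np)
    region and an inclusive one for the protein region, so that the shared
    boundary at 2000.0 Da belongs to exactly one region (protein).
    """

    name: str
    low: float
    high: float
    high_inclusive: bool

    def contains(self, mz: float) -> bool:
        if self.high_inclusive:
            return self.low <= mz <= self.high
        return self.low <= mz < self.high


#: Small-protein fingerprint region used for pseudo-phylogenetic grouping.
PROTEIN_REGION = MassRegion("protein", 2000.0, 15000.0, high_inclusive=True)
#: Small-molecule (natural product) region used for metabolite networks.
NP_REGION = MassRegion("np", 200.0, 2000.0, high_inclusive=False)

REGIONS: dict[str, MassRegion] = {r.name: r for r in (PROTEIN_REGION, NP_REGION)}


@dataclass
class ConsensusPeakList:
    """Per-isolate peaks surviving replicate agreement.

    ``presence[i]`` is the fraction of technical replicates in which
    ``peaks[i]`` was observed, in (0, 1].  ``region`` is ``None`` before
    region splitting, afterwards one of ``"protein"`` / ``"np"``.
    """

    isolate_id: str
    peaks: list[Peak]
    presence: list[float]
    n_replicates: int
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.peaks) != len(self.presence):
            raise ValueError("peaks and presence must have equal length")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        for p in self.presence:
            if not 0 < p <= 1:
                raise ValueError(f"presence must lie in (0, 1], got {p}")
        if self.region is not None:
            reg = REGIONS[self.region]
            for pk in self.peaks:
                if not reg.contains(pk.mz):
                    raise ValueError(
                        f"peak mz {pk.mz} outside {self.region} region bounds"
                    )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> list[float]:
        return [p.mz for p in self.peaks]


def sorted_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Sort peaks by m/z, collapsing exact-duplicate m/z keeping max intensity."""
    best: dict[float, Peak] = {}
    for p in peaks:
        cur = best.get(p.mz)
        if cur is None or p.intensity > cur.intensity:
            best[p.mz] = p
    return [best[mz] for mz in sorted(best)]
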