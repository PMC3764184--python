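"""Dual-FDR-threshold classification of binding events.

A binding event called at 1% FDR in one tissue is *tissue-specific* when it
is not even called at the permissive 25% FDR in the other tissue, and
*tissue-shared* when it overlaps (>=1 bp) any 25%-FDR call there.  This
deliberately ignores quantitative differences in binding strength: the
permissive opposite-tissue tier must be completely empty at the locus for a
specific call, which makes the classification robust to peaks hovering
around the stringent threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from .core import (
    GenomicInterval,
    IntervalIndex,
    ScoredPeak,
    ValidationError,
    merge_intervals,
)


class Label(str, Enum):
    SHARED = "SHARED"
    SPECIFIC = "SPECIFIC"


@dataclass
class DualTierPeakSet:
    """One tissue's peak calls at both FDR tiers for a single factor.

    Invariant (enforced): every stringent (FDR1) peak overlaps at least one
    permissive (FDR25) peak — the permissive tier is a superset by
    construction of threshold nesting.
    """

    factor: str
    tissue: str
    fdr1_peaks: list[ScoredPeak]
    fdr25_peaks: list[ScoredPeak]

    def __post_init__(self) -> None:
        for p in self.fdr1_peaks:
            if p.fdr_tier != 1:
                raise ValidationError(f"peak {p.interval} in fdr1_peaks has tier {p.fdr_tier}")
        for p in self.fdr25_peaks:
            if p.fdr_tier != 25:
                raise ValidationError(f"peak {p.interval} in fdr25_peaks has tier {p.fdr_tier}")
        idx = IntervalIndex(self.fdr25_peaks)
        for p in self.fdr1_peaks:
            if not idx.any_overlap(p):
                raise ValidationError(
                    f"{self.factor}/{self.tissue}: FDR1 peak "
                    f"{p.chrom}:{p.start}-{p.end} has no overlapping FDR25 peak "
                    "(threshold nesting violated)"
                )


@dataclass(frozen=True)
class SpecificityCall:
    """An FDR1 peak labelled SHARED or SPECIFIC relative to a partner tissue."""

    peak: ScoredPeak
    label: Label
    home_tissue: str
    partner_tissue: str


@dataclass
class ClassificationResult:
    factor: str
    calls: dict[str, list[SpecificityCall]]  # tissue -> calls for its FDR1 peaks

    def counts(self) -> dict[str, tuple[int, int]]:
        """Per tissue: (shared, specific) tallies."""
        out = {}
        for tissue, calls in self.calls.items():
            shared = sum(1 for c in calls if c.label is Label.SHARED)
            out[tissue] = (shared, len(calls) - shared)
        return out

    def subset(self, tissue: str, label: Label) -> list[ScoredPeak]:
        return [c.peak for c in self.calls[tissue] if c.label is label]


def classify(set_a: DualTierPeakSet, set_b: DualTierPeakSet) -> ClassificationResult:
    """Label every FDR1 peak of each tissue as SHARED or SPECIFIC.

    A peak from tissue A is SPECIFIC iff it overlaps none of tissue B's
    FDR25 peaks, SHARED otherwise; symmetrically for B.  Both sets must
    carry the same factor.
    """
    if set_a.factor != set_b.factor:
        raise ValidationError(
            f"cannot classify across factors {set_a.factor!r} vs {set_b.factor!r}"
        )
    if set_a.tissue == set_b.tissue:
        raise ValidationError(f"both peak sets are from tissue {set_a.tissue!r}")
    result: dict[str, list[SpecificityCall]] = {}
    for home, partner in ((set_a, set_b), (set_b, set_a)):
        idx = IntervalIndex(partner.fdr25_peaks)
        calls = [
            SpecificityCall(
                peak=p,
                label=Label.SHARED if idx.any_overlap(p) else Label.SPECIFIC,
                home_tissue=home.tissue,
                partner_tissue=partner.tissue,
            )
            for p in home.fdr1_peaks
        ]
        result[home.tissue] = calls
    return ClassificationResult(factor=set_a.factor, calls=result)


def shared_consensus(result: ClassificationResult) -> list[GenomicInterval]:
    """One merged tissue-shared region list for downstream modules.

    Union of the SHARED-labelled FDR1 peaks of both tissues, merged
    single-linkage, so each shared locus appears once even when both
    tissues called it.
    """
    shared = [c.peak for calls in result.calls.values() for c in calls
              if c.label is Label.SHARED]
    return merge_intervals(shared)
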