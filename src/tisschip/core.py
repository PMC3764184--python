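"""Genomic data model and interval primitives.

All coordinates are 0-based half-open ``[start, end)`` throughout the
package; BED input is native, GFF3 is converted on read.  Overlap means at
least one shared base, so abutting intervals never overlap.  Chromosome
names are matched by exact string comparison (no "chr" aliasing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

STRANDS = ("+", "-", ".")

#: The five-colour chromatin-state alphabet.
CHROMATIN_STATES = ("YELLOW", "RED", "BLUE", "GREEN", "BLACK")

#: Bucket for peaks whose centre falls outside every segmentation interval.
UNASSIGNED_STATE = "UNASSIGNED"


class ValidationError(ValueError):
    """Raised when a record violates a data-model invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Peak centre, ``floor((start+end)/2)``."""
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class ScoredPeak:
    """A called binding event with factor, tissue and FDR tier.

    ``fdr_tier`` is the percent false-discovery rate of the call: 1 for the
    stringent tier, 25 for the permissive tier used by the "not called"
    criterion of the specificity rule.  ``score`` is a dimensionless
    enrichment score.
    """

    interval: GenomicInterval
    factor: str = ""
    tissue: str = ""
    fdr_tier: int = 1
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.fdr_tier not in (1, 25):
            raise ValidationError(f"fdr_tier must be 1 or 25, got {self.fdr_tier}")
        if not np.isfinite(self.score):
            raise ValidationError("peak score must be finite")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: body span, strand-aware TSS and exon list."""

    gene_id: str
    body: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        for ex in self.exons:
            if ex.chrom != self.body.chrom or ex.start < self.body.start or ex.end > self.body.end:
                raise ValidationError(f"gene {self.gene_id}: exon {ex} outside body {self.body}")

    @property
    def tss(self) -> int:
        """0-based TSS position: body.start on +, body.end - 1 on -."""
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def chrom(self) -> str:
        return self.body.chrom


@dataclass
class GenomeAssembly:
    """Chromosome sizes plus an optional nucleotide sequence per chromosome."""

    chrom_sizes: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")
        if self.sequence is not None:
            for name, seq in self.sequence.items():
                expected = self.chrom_sizes.get(name)
                if expected is None:
                    raise ValidationError(f"sequence for unknown chromosome {name}")
                if len(seq) != expected:
                    raise ValidationError(
                        f"sequence length {len(seq)} != declared size {expected} for {name}"
                    )

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def validate_interval(self, iv: GenomicInterval) -> None:
        size = self.chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValidationError(f"interval on undeclared chromosome {iv.chrom}")
        if iv.end > size:
            raise ValidationError(f"interval {iv} exceeds chromosome length {size}")

    def fetch(self, iv: GenomicInterval) -> str:
        """Return the forward-strand sequence under ``iv``."""
        if self.sequence is None:
            raise ValidationError("assembly carries no sequence")
        self.validate_interval(iv)
        return self.sequence[iv.chrom][iv.start : iv.end]


@dataclass
class Segmentation:
    """Non-overlapping labelled intervals partitioning (part of) a genome.

    Labels are drawn from the five-state chromatin alphabet by default; a
    different alphabet may be supplied for generic labelled segmentations.
    """

    intervals: list[GenomicInterval]
    alphabet: tuple[str, ...] = CHROMATIN_STATES

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            if iv.name not in self.alphabet:
                raise ValidationError(f"segment label {iv.name!r} not in {self.alphabet}")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValidationError(f"segments overlap: {a} and {b}")

    def label_at(self, chrom: str, pos: int) -> str:
        """State label covering ``pos``, or UNASSIGNED if in a gap."""
        idx = getattr(self, "_index", None)
        if idx is None:
            idx = {}
            for iv in self.intervals:
                idx.setdefault(iv.chrom, ([], [], []))
            for iv in sorted(self.intervals, key=lambda x: (x.chrom, x.start)):
                s, e, lab = idx[iv.chrom]
                s.append(iv.start)
                e.append(iv.end)
                lab.append(iv.name)
            idx = {
                c: (np.asarray(s), np.asarray(e), lab) for c, (s, e, lab) in idx.items()
            }
            object.__setattr__(self, "_index", idx)
        if chrom not in idx:
            return UNASSIGNED_STATE
        starts, ends, labels = idx[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return UNASSIGNED_STATE

    def state_lengths(self) -> dict[str, int]:
        out = {s: 0 for s in self.alphabet}
        for iv in self.intervals:
            out[iv.name] += len(iv)
        return out

    def intervals_of(self, state: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.name == state]


@dataclass
class SignalTrack:
    """Dense per-base numeric signal; NaN marks missing positions.

    Suited to desk-scale genomes (arrays are one float per base).  Values
    are e.g. PhastCons-style conservation probabilities in [0, 1] or a
    binary pairwise-identity indicator.
    """

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"track for {name} is not 1-D")
            finite = arr[~np.isnan(arr)]
            if finite.size and not np.all(np.isfinite(finite)):
                raise ValidationError(f"track for {name} contains non-finite values")
            self.values[name] = arr

    @classmethod
    def empty(cls, assembly: GenomeAssembly) -> "SignalTrack":
        return cls({c: np.full(n, np.nan) for c, n in assembly.chrom_sizes.items()})

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); out-of-bounds positions are NaN."""
        out = np.full(end - start, np.nan)
        arr = self.values.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, arr.size)
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


@dataclass(frozen=True)
class EnhancerFragment:
    """A catalogued DNA fragment with per-tissue reporter-activity flags."""

    id: str
    interval: GenomicInterval
    activity: Mapping[str, bool]

    REQUIRED_TISSUES = ("eye", "antenna", "leg", "wing")

    def __post_init__(self) -> None:
        missing = [t for t in self.REQUIRED_TISSUES if t not in self.activity]
        if missing:
            raise ValidationError(f"fragment {self.id}: missing activity flags {missing}")


@dataclass
class GeneSetLibrary:
    """Named gene-identifier sets over a declared universe (GO-term-like)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Interval primitives
# ---------------------------------------------------------------------------


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by the two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _as_interval(x) -> GenomicInterval:
    return x.interval if isinstance(x, ScoredPeak) else x


def merge_intervals(intervals: Iterable[GenomicInterval | ScoredPeak]) -> list[GenomicInterval]:
    """Single-linkage merge of overlapping intervals.

    Returns the union as sorted, non-overlapping intervals.  Abutting
    intervals (sharing no base) are NOT merged, per the half-open overlap
    contract.
    """
    ivs = sorted((_as_interval(x) for x in intervals), key=lambda v: (v.chrom, v.start, v.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


class IntervalIndex:
    """Overlap queries against a fixed interval set via sorted merged arrays.

    Built once from any iterable of intervals/peaks; ``any_overlap`` asks
    whether a query interval shares >=1 base with the set.
    """

    def __init__(self, intervals: Iterable[GenomicInterval | ScoredPeak]):
        merged = merge_intervals(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.asarray([iv.start for iv in ivs])
            self._ends[chrom] = np.asarray([iv.end for iv in ivs])

    def any_overlap(self, query: GenomicInterval | ScoredPeak) -> bool:
        q = _as_interval(query)
        starts = self._starts.get(q.chrom)
        if starts is None:
            return False
        ends = self._ends[q.chrom]
        # first merged interval with end > q.start; overlaps iff it starts before q.end
        i = int(np.searchsorted(ends, q.start, side="right"))
        return i < starts.size and starts[i] < q.end
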