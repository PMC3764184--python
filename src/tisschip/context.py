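"""Conservation profiles, ultraconserved elements and chromatin-state enrichment.

Profiles average a per-base signal (e.g. PhastCons) over a fixed window
around every peak centre.  Ultraconserved elements are maximal runs of
>=50 perfectly conserved bases in a binary pairwise-identity track, or an
interval set consumed directly from BED.  Chromatin-state enrichment
assigns each peak the five-colour state at its centre (exclusive, so
fractions sum to 1) and tests each state with the binned hypergeometric
co-occurrence model; an any-overlap counting mode is available since a
wide peak can touch several segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CHROMATIN_STATES,
    UNASSIGNED_STATE,
    GenomeAssembly,
    GenomicInterval,
    IntervalIndex,
    ScoredPeak,
    Segmentation,
    SignalTrack,
    ValidationError,
)
from .overlap import OverlapUniverse, cooccurrence_test


def _iv(x) -> GenomicInterval:
    return x.interval if isinstance(x, ScoredPeak) else x


@dataclass
class ProfileResult:
    """Per-offset mean signal around peak centres.

    positions run -halfwidth..+halfwidth; the mean at an offset is over
    the peaks that have data there (missing/NaN positions are excluded,
    not zero-filled).
    """

    positions: np.ndarray
    mean_score: np.ndarray
    n_contributing: np.ndarray


def profile_scores(peaks: Sequence, track: SignalTrack, halfwidth: int = 500) -> ProfileResult:
    """Average signal in a (2*halfwidth+1)-base window around peak centres."""
    width = 2 * halfwidth + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=int)
    for p in peaks:
        iv = _iv(p)
        c = iv.center
        vals = track.slice(iv.chrom, c - halfwidth, c + halfwidth + 1)
        ok = ~np.isnan(vals)
        total[ok] += vals[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ProfileResult(positions=np.arange(-halfwidth, halfwidth + 1),
                         mean_score=mean, n_contributing=count)


def find_perfect_runs(identity_track: SignalTrack, min_len: int = 50) -> list[GenomicInterval]:
    """Maximal runs of >= min_len perfectly conserved bases.

    The track must be binary (1 = identical base across species, 0 = not;
    NaN = no alignment, treated as 0).  A run of exactly min_len bases
    qualifies; min_len - 1 does not.
    """
    out = []
    for chrom, arr in identity_track.values.items():
        vals = np.nan_to_num(arr, nan=0.0)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError(f"identity track for {chrom} is not binary")
        ones = vals == 1.0
        padded = np.concatenate([[False], ones, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def uce_overlap_fraction(peaks: Sequence, uces: Sequence[GenomicInterval]) -> float:
    """Fraction of peaks overlapping >=1 ultraconserved element."""
    if not peaks:
        return float("nan")
    idx = IntervalIndex(uces)
    return sum(1 for p in peaks if idx.any_overlap(_iv(p))) / len(peaks)


@dataclass(frozen=True)
class StateEnrichmentRow:
    state: str
    peak_count: int
    fraction: float
    expected_fraction: float
    p_value: float
    neg_log_p: float


def state_enrichment(
    peaks: Sequence,
    segmentation: Segmentation,
    assembly: GenomeAssembly,
    bin_width: int = 1000,
    mode: str = "center",
) -> list[StateEnrichmentRow]:
    """Chromatin-state composition and enrichment of a peak class.

    mode="center" (default): each peak counts once, for the state at its
    centre; fractions over the five states (plus UNASSIGNED for gaps) sum
    to 1.  mode="any": a peak counts for every state it overlaps, so
    fractions may sum to >1.  expected_fraction is the state's share of
    the genome; the p-value comes from the binned hypergeometric
    co-occurrence test of the peak set against that state's intervals.
    """
    if not peaks:
        raise ValidationError("state_enrichment needs >=1 peak")
    counts = {s: 0 for s in (*CHROMATIN_STATES, UNASSIGNED_STATE)}
    if mode == "center":
        for p in peaks:
            iv = _iv(p)
            counts[segmentation.label_at(iv.chrom, iv.center)] += 1
    elif mode == "any":
        indexes = {s: IntervalIndex(segmentation.intervals_of(s)) for s in CHROMATIN_STATES}
        for p in peaks:
            hit_any = False
            for s, idx in indexes.items():
                if idx.any_overlap(_iv(p)):
                    counts[s] += 1
                    hit_any = True
            if not hit_any:
                counts[UNASSIGNED_STATE] += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if counts[UNASSIGNED_STATE]:
        warnings.warn(f"{counts[UNASSIGNED_STATE]} peak(s) in segmentation gaps "
                      "assigned to UNASSIGNED")
    lengths = segmentation.state_lengths()
    genome = assembly.total_length
    uni = OverlapUniverse(assembly, bin_width)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for state in CHROMATIN_STATES:
            r = cooccurrence_test(peaks, segmentation.intervals_of(state),
                                  assembly, universe=uni)
            rows.append(StateEnrichmentRow(
                state=state, peak_count=counts[state],
                fraction=counts[state] / len(peaks),
                expected_fraction=lengths[state] / genome,
                p_value=r.p_value, neg_log_p=r.neg_log_p))
    if counts[UNASSIGNED_STATE]:
        rows.append(StateEnrichmentRow(
            state=UNASSIGNED_STATE, peak_count=counts[UNASSIGNED_STATE],
            fraction=counts[UNASSIGNED_STATE] / len(peaks),
            expected_fraction=float("nan"), p_value=1.0, neg_log_p=0.0))
    return rows


def state_enrichment_table(rows: list[StateEnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
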