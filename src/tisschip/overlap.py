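"""Interval co-occurrence statistics.

The null model bins the genome into fixed-width units (default 1 kb); a
bin is "hit" by a set when >=1 of its intervals overlaps the bin.  With N
bins total, n hit by the query set and K by the reference set, the number
hit by both under independence is hypergeometric(N, K, n), giving an
upper-tail co-occurrence p-value, an expected overlap nK/N, and an
observed/expected ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    EnhancerFragment,
    GenomeAssembly,
    GenomicInterval,
    IntervalIndex,
    ScoredPeak,
    ValidationError,
    merge_intervals,
)

#: Smallest p-value reported; -ln(p) is capped accordingly.
TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class CooccurrenceResult:
    observed: int
    expected: float
    p_value: float
    neg_log_p: float
    obs_exp_ratio: float
    n_bins: int
    n_query: int
    n_reference: int


class OverlapUniverse:
    """Fixed-width genome bins with per-set hit masks."""

    def __init__(self, assembly: GenomeAssembly, bin_width: int = 1000):
        if bin_width < 1:
            raise ValidationError("bin_width must be >= 1")
        if not assembly.chrom_sizes:
            raise ValidationError("empty assembly")
        self.bin_width = bin_width
        self._offsets: dict[str, int] = {}
        total = 0
        for chrom, size in assembly.chrom_sizes.items():
            self._offsets[chrom] = total
            total += -(-size // bin_width)  # ceil
        self.n_bins = total

    def hit_mask(self, intervals: Iterable[GenomicInterval | ScoredPeak]) -> np.ndarray:
        mask = np.zeros(self.n_bins, dtype=bool)
        w = self.bin_width
        for iv in intervals:
            iv = iv.interval if isinstance(iv, ScoredPeak) else iv
            off = self._offsets.get(iv.chrom)
            if off is None:
                raise ValidationError(f"interval on undeclared chromosome {iv.chrom}")
            mask[off + iv.start // w : off + (iv.end - 1) // w + 1] = True
        return mask


def cooccurrence_test(
    set_a: Sequence,
    set_b: Sequence,
    assembly: GenomeAssembly,
    bin_width: int = 1000,
    universe: OverlapUniverse | None = None,
) -> CooccurrenceResult:
    """Hypergeometric co-occurrence of two interval sets on binned genome.

    Empty input sets give p = 1 with a NaN ratio (and a warning) rather
    than an error, so sparse classes degrade gracefully in matrices.
    """
    uni = universe or OverlapUniverse(assembly, bin_width)
    a = uni.hit_mask(set_a)
    b = uni.hit_mask(set_b)
    n, big_k = int(a.sum()), int(b.sum())
    k = int((a & b).sum())
    big_n = uni.n_bins
    if n == 0 or big_k == 0:
        warnings.warn("empty interval set in cooccurrence_test; p=1, ratio NaN")
        return CooccurrenceResult(observed=0, expected=0.0, p_value=1.0,
                                  neg_log_p=0.0, obs_exp_ratio=float("nan"),
                                  n_bins=big_n, n_query=n, n_reference=big_k)
    expected = n * big_k / big_n
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    p = min(max(p, TINY_P), 1.0)
    return CooccurrenceResult(
        observed=k,
        expected=expected,
        p_value=p,
        neg_log_p=float(-np.log(p)),
        obs_exp_ratio=k / expected,
        n_bins=big_n,
        n_query=n,
        n_reference=big_k,
    )


def pairwise_matrix(
    sets: Mapping[str, Sequence],
    assembly: GenomeAssembly,
    bin_width: int = 1000,
) -> pd.DataFrame:
    """All-against-all co-occurrence for labelled interval sets.

    Returns a long-format DataFrame (query, reference, observed, expected,
    p_value, neg_log_p, obs_exp_ratio).  Rows are the query set; the test
    is symmetric in the margins so (a, b) and (b, a) carry the same p.
    """
    if len(sets) < 2:
        raise ValidationError("pairwise_matrix needs >=2 sets")
    uni = OverlapUniverse(assembly, bin_width)
    rows = []
    names = list(sets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for qa in names:
            for qb in names:
                if qa == qb:
                    continue
                r = cooccurrence_test(sets[qa], sets[qb], assembly, universe=uni)
                rows.append({"query": qa, "reference": qb, "observed": r.observed,
                             "expected": r.expected, "p_value": r.p_value,
                             "neg_log_p": r.neg_log_p, "obs_exp_ratio": r.obs_exp_ratio})
    return pd.DataFrame(rows)


TISSUE_FLAGS = ("eye", "antenna", "leg", "wing")


def summarize_enhancer_overlap(
    calls: Sequence,
    catalog: Sequence[EnhancerFragment],
) -> pd.DataFrame:
    """Per-tissue summary of enhancer-catalog fragments bound by peaks.

    A fragment is *bound* iff >=1 call overlaps it (counted once no matter
    how many peaks fall in it).  For each tissue activity flag the table
    reports the number of bound fragments active in that tissue, the
    fraction of bound fragments that are active (the headline percentages,
    e.g. 147 of 164 wing-active = 89.6%), and an observed/expected ratio
    against the catalog-wide activity rate.  Also reports ``unique_crms``:
    the number of regions after merging partially overlapping bound
    fragments.
    """
    if not catalog:
        raise ValidationError("empty enhancer catalog")
    idx = IntervalIndex(calls)
    bound = [f for f in catalog if idx.any_overlap(f.interval)]
    n_bound = len(bound)
    unique_crms = len(merge_intervals([f.interval for f in bound]))
    rows = []
    for tissue in TISSUE_FLAGS:
        active_and_bound = sum(1 for f in bound if f.activity[tissue])
        catalog_rate = sum(1 for f in catalog if f.activity[tissue]) / len(catalog)
        fraction = active_and_bound / n_bound if n_bound else float("nan")
        expected = n_bound * catalog_rate
        rows.append({
            "tissue": tissue,
            "bound_fragments": n_bound,
            "active_and_bound": active_and_bound,
            "fraction": fraction,
            "obs_exp": active_and_bound / expected if expected else float("nan"),
            "unique_crms": unique_crms,
        })
    return pd.DataFrame(rows)
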