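"""Genomic-region breakdown, target-gene assignment and gene-set enrichment.

Each peak receives exactly one region label, decided at the peak centre
with precedence PROMOTER > EXON > INTRON > INTERGENIC, so per-class region
fractions sum to 1.  The promoter is the strand-aware 1 kb window upstream
of a TSS.  Genes are partitioned by the specificity labels of the peaks
targeting them into shared-only, shared-plus-specific and specific-only
regulatory-logic classes, and gene lists are tested against a GMT library
with upper-tail hypergeometric p-values and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GeneSetLibrary, ScoredPeak, ValidationError
from .specificity import Label, SpecificityCall


class RegionLabel(str, Enum):
    PROMOTER = "PROMOTER"
    EXON = "EXON"
    INTRON = "INTRON"
    INTERGENIC = "INTERGENIC"


class LogicClass(str, Enum):
    SHARED_ONLY = "SHARED_ONLY"
    SHARED_PLUS_SPECIFIC = "SHARED_PLUS_SPECIFIC"
    SPECIFIC_ONLY = "SPECIFIC_ONLY"


def _center(x) -> tuple[str, int]:
    iv = x.interval if isinstance(x, ScoredPeak) else x
    return iv.chrom, iv.center


def _in_promoter(pos: int, gene: GeneModel, window: int) -> bool:
    # + strand: [tss-window, tss); - strand: (tss, tss+window]
    if gene.strand == "+":
        return gene.tss - window <= pos < gene.tss
    return gene.tss < pos <= gene.tss + window


def assign_region(
    peak,
    gene_models: Sequence[GeneModel],
    promoter_window: int = 1000,
) -> RegionLabel:
    """Region label of one peak, decided at its centre."""
    chrom, pos = _center(peak)
    in_exon = in_body = False
    for g in gene_models:
        if g.chrom != chrom:
            continue
        if _in_promoter(pos, g, promoter_window):
            return RegionLabel.PROMOTER
        if g.body.start <= pos < g.body.end:
            in_body = True
            if any(ex.start <= pos < ex.end for ex in g.exons):
                in_exon = True
    if in_exon:
        return RegionLabel.EXON
    if in_body:
        return RegionLabel.INTRON
    return RegionLabel.INTERGENIC


def region_breakdown(
    peaks: Sequence,
    gene_models: Sequence[GeneModel],
    promoter_window: int = 1000,
) -> dict[RegionLabel, float]:
    """Fraction of peaks per region label; fractions sum to 1."""
    if not peaks:
        raise ValidationError("region_breakdown needs >=1 peak")
    counts = {label: 0 for label in RegionLabel}
    for p in peaks:
        counts[assign_region(p, gene_models, promoter_window)] += 1
    return {label: c / len(peaks) for label, c in counts.items()}


@dataclass
class GenePeakAssignment:
    gene_id: str
    calls: list[SpecificityCall]
    logic_class: LogicClass


def _logic_class(labels: Iterable[Label]) -> LogicClass:
    labels = set(labels)
    if labels == {Label.SHARED}:
        return LogicClass.SHARED_ONLY
    if labels == {Label.SPECIFIC}:
        return LogicClass.SPECIFIC_ONLY
    return LogicClass.SHARED_PLUS_SPECIFIC


def assign_targets(
    calls: Sequence[SpecificityCall],
    gene_models: Sequence[GeneModel],
    max_distance: int = 10000,
) -> list[GenePeakAssignment]:
    """Assign labelled peaks to target genes and compute logic classes.

    A gene is targeted by a peak iff the peak overlaps the gene body or
    lies within ``max_distance`` of its TSS; one peak may target several
    genes.  Known limitation: distal regulation beyond the window (real
    enhancers can act at >30 kb) is missed; widen ``max_distance`` to
    trade precision for recall.
    """
    by_gene: dict[str, list[SpecificityCall]] = {}
    for g in gene_models:
        for c in calls:
            iv = c.peak.interval
            if iv.chrom != g.chrom:
                continue
            hits_body = iv.start < g.body.end and g.body.start < iv.end
            near_tss = iv.start - max_distance <= g.tss < iv.end + max_distance
            if hits_body or near_tss:
                by_gene.setdefault(g.gene_id, []).append(c)
    return [
        GenePeakAssignment(gene_id=gid, calls=cs,
                           logic_class=_logic_class(c.label for c in cs))
        for gid, cs in by_gene.items()
    ]


def gene_set_enrichment(
    gene_list: Iterable[str],
    universe: Iterable[str],
    library: GeneSetLibrary,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    p = P(X >= hits) with X ~ hypergeometric(universe, set, list); BH FDR
    across the sets of the library.  Set members outside the declared
    universe are ignored.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    gene_list = frozenset(gene_list)
    if not gene_list <= universe:
        raise ValidationError("gene list contains identifiers outside the universe")
    rows = []
    for name, members in library.sets.items():
        members = members & universe
        hits = len(members & gene_list)
        p = float(stats.hypergeom.sf(hits - 1, len(universe), len(members), len(gene_list)))
        rows.append({"set_name": name, "hits": hits, "set_size": len(members),
                     "list_size": len(gene_list), "universe_size": len(universe),
                     "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["bh_fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df
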