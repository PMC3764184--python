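"""Region breakdown, target assignment, logic partition, gene-set enrichment."""

from math import comb

import numpy as np
import pytest

from tisschip.annotation import (
    LogicClass,
    RegionLabel,
    assign_region,
    assign_targets,
    gene_set_enrichment,
    region_breakdown,
)
from tisschip.core import GeneModel, GeneSetLibrary, GenomicInterval, ValidationError
from tisschip.specificity import Label, SpecificityCall
from tests.conftest import make_peak


def _gene(gid, chrom, start, end, strand, exon_spans=None):
    body = GenomicInterval(chrom, start, end)
    exons = tuple(GenomicInterval(chrom, s, e) for s, e in (exon_spans or [(start, end)]))
    return GeneModel(gene_id=gid, body=body, strand=strand, exons=exons)


GENES = [
    # + strand gene: tss 2000, promoter [1000, 2000)
    _gene("plus", "c", 2000, 6000, "+", [(2000, 2500), (5000, 6000)]),
    # - strand gene: tss 9999, promoter (9999, 10999]
    _gene("minus", "c", 8000, 10_000, "-", [(8000, 10_000)]),
]


@pytest.mark.parametrize("span,expect", [
    ((1200, 1400), RegionLabel.PROMOTER),     # centre 1300 in [1000, 2000)
    ((900, 1100), RegionLabel.PROMOTER),      # centre 1000, window start
    ((800, 1100), RegionLabel.INTERGENIC),    # centre 950 < 1000
    ((2100, 2300), RegionLabel.EXON),         # centre inside first exon
    ((3000, 3200), RegionLabel.INTRON),       # centre between exons
    ((10_200, 10_400), RegionLabel.PROMOTER),  # minus-strand upstream window
    ((11_500, 11_700), RegionLabel.INTERGENIC),
    ((9_000, 9_200), RegionLabel.EXON),
])
def test_assign_region_window_and_precedence(span, expect):
    assert assign_region(make_peak("c", *span), GENES) is expect


def test_promoter_beats_exon():
    # exon of one gene sitting <1 kb upstream of another gene's TSS
    genes = [
        _gene("host", "c", 0, 3000, "+", [(0, 3000)]),
        _gene("next", "c", 3500, 6000, "+"),  # promoter [2500, 3500)
    ]
    peak = make_peak("c", 2800, 3000)  # centre 2900: in host exon AND next promoter
    assert assign_region(peak, genes) is RegionLabel.PROMOTER


def test_assign_region_matches_exhaustive_oracle():
    """1 bp peaks at every position agree with a re-derived rule."""
    genes = GENES
    for pos in range(0, 12_000, 7):
        got = assign_region(GenomicInterval("c", pos, pos + 1), genes)
        # independent oracle
        if 1000 <= pos < 2000 or 10_000 <= pos <= 10_999:
            want = RegionLabel.PROMOTER
        elif 2000 <= pos < 2500 or 5000 <= pos < 6000 or 8000 <= pos < 10_000:
            want = RegionLabel.EXON
        elif 2500 <= pos < 5000:
            want = RegionLabel.INTRON
        else:
            want = RegionLabel.INTERGENIC
        assert got is want, pos


def test_region_breakdown_sums_to_one():
    peaks = [make_peak("c", 1200, 1400), make_peak("c", 1300, 1500),
             make_peak("c", 20_000, 20_200), make_peak("c", 30_000, 30_200)]
    frac = region_breakdown(peaks, GENES)
    assert frac[RegionLabel.PROMOTER] == 0.5
    assert frac[RegionLabel.INTERGENIC] == 0.5
    assert abs(sum(frac.values()) - 1) < 1e-12
    with pytest.raises(ValidationError):
        region_breakdown([], GENES)


def _call(span, label, tissue="W"):
    return SpecificityCall(peak=make_peak("c", *span, tissue=tissue), label=label,
                           home_tissue=tissue, partner_tissue="EA")


def test_assign_targets_logic_classes():
    gene = _gene("g", "c", 50_000, 55_000, "+")
    shared = _call((49_000, 49_200), Label.SHARED)
    specific = _call((52_000, 52_200), Label.SPECIFIC)
    far = _call((90_000, 90_200), Label.SPECIFIC)
    only_shared = assign_targets([shared, far], [gene])
    assert len(only_shared) == 1
    assert only_shared[0].logic_class is LogicClass.SHARED_ONLY
    both = assign_targets([shared, specific], [gene])
    assert both[0].logic_class is LogicClass.SHARED_PLUS_SPECIFIC
    assert assign_targets([specific], [gene])[0].logic_class is LogicClass.SPECIFIC_ONLY


def test_assign_targets_window_rule():
    gene = _gene("g", "c", 50_000, 55_000, "+")  # tss 50000
    inside_window = _call((39_900, 40_100), Label.SHARED)   # within 10 kb of tss
    outside = _call((39_500, 39_700), Label.SHARED)         # >10 kb away
    body_hit = _call((54_900, 55_200), Label.SHARED)        # overlaps body end
    res = assign_targets([inside_window, outside, body_hit], [gene])
    assert len(res) == 1 and len(res[0].calls) == 2


@pytest.mark.parametrize("trial", range(5))
def test_logic_partition_matches_bruteforce(trial):
    rng = np.random.default_rng(300 + trial)
    genes = [_gene(f"g{i}", "c", int(s), int(s) + 4000, "+")
             for i, s in enumerate(rng.choice(np.arange(0, 400_000, 20_000),
                                              size=15, replace=False))]
    calls = [_call((int(s), int(s) + 200),
                   Label.SHARED if rng.random() < 0.5 else Label.SPECIFIC)
             for s in rng.integers(0, 420_000, size=60)]
    res = assign_targets(calls, genes)
    # partition is exact and matches a label-multiset re-derivation
    for a in res:
        gene = next(g for g in genes if g.gene_id == a.gene_id)
        want = set()
        for c in calls:
            iv = c.peak.interval
            if (iv.start < gene.body.end and gene.body.start < iv.end) or \
                    (iv.start - 10_000 <= gene.tss < iv.end + 10_000):
                want.add(c.label)
        assert set(x.label for x in a.calls) == want
        expect = (LogicClass.SHARED_ONLY if want == {Label.SHARED} else
                  LogicClass.SPECIFIC_ONLY if want == {Label.SPECIFIC} else
                  LogicClass.SHARED_PLUS_SPECIFIC)
        assert a.logic_class is expect
    targeted = {a.gene_id for a in res}
    by_class = {}
    for a in res:
        by_class.setdefault(a.logic_class, set()).add(a.gene_id)
    assert set.union(set(), *by_class.values()) == targeted
    assert sum(len(v) for v in by_class.values()) == len(targeted)


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------


def _library(**sets):
    return GeneSetLibrary(sets={k: frozenset(v) for k, v in sets.items()})


def test_gene_set_exact_tail():
    """Universe 100, set 10, list 10, 5 hits: exact upper-tail summation."""
    universe = [f"u{i}" for i in range(100)]
    target = universe[:10]
    gene_list = target[:5] + universe[50:55]
    lib = _library(hit_set=target)
    row = gene_set_enrichment(gene_list, universe, lib).iloc[0]
    oracle = sum(comb(10, i) * comb(90, 10 - i) for i in range(5, 11)) / comb(100, 10)
    assert row["p_value"] == pytest.approx(oracle, rel=1e-10)
    assert row["hits"] == 5


def test_gene_set_degenerate_cases():
    universe = [f"u{i}" for i in range(40)]
    lib = _library(s1=universe[:10], s2=universe[10:20])
    # no hits -> p ~ 1
    no_hit = gene_set_enrichment(universe[20:25], universe, lib)
    assert (no_hit[no_hit.set_name == "s1"]["p_value"] >= 0.9).all()
    # list = universe -> saturation, p = 1 everywhere
    full = gene_set_enrichment(universe, universe, lib)
    assert (full["p_value"] == 1.0).all()
    with pytest.raises(ValidationError):
        gene_set_enrichment(["u1"], [], lib)
    with pytest.raises(ValidationError):
        gene_set_enrichment(["not_in_universe"], universe, lib)


def test_bh_matches_textbook_stepup():
    rng = np.random.default_rng(11)
    universe = [f"u{i}" for i in range(200)]
    sets = {f"s{j}": frozenset(rng.choice(universe, size=20, replace=False))
            for j in range(15)}
    lib = GeneSetLibrary(sets=sets)
    gene_list = list(rng.choice(universe, size=30, replace=False))
    df = gene_set_enrichment(gene_list, universe, lib)
    p = df["p_value"].to_numpy()
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    assert np.allclose(df["bh_fdr"].to_numpy(), adj)
    assert (df["bh_fdr"] >= df["p_value"] - 1e-15).all()
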