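"""Data model, interval primitives and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tisschip import io as tio
from tisschip.core import (
    GenomeAssembly,
    GenomicInterval,
    IntervalIndex,
    ScoredPeak,
    SignalTrack,
    ValidationError,
    merge_intervals,
    overlap_length,
    overlaps,
)
from tests.conftest import make_peak


@pytest.mark.parametrize("a,b,expect_overlap,expect_len", [
    ((0, 10), (10, 20), False, 0),   # abutting: half-open, no shared base
    ((0, 10), (9, 20), True, 1),
    ((0, 10), (2, 5), True, 3),
    ((5, 8), (0, 20), True, 3),
])
def test_overlap_halfopen(a, b, expect_overlap, expect_len):
    ia = GenomicInterval("chr1", *a)
    ib = GenomicInterval("chr1", *b)
    assert overlaps(ia, ib) is expect_overlap
    assert overlap_length(ia, ib) == expect_len
    assert overlaps(ib, ia) is expect_overlap


def test_overlap_requires_same_chrom():
    assert not overlaps(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10))


@pytest.mark.parametrize("start,end", [(200, 100), (5, 5), (-1, 10)])
def test_interval_validation(start, end):
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", start, end)


def test_scored_peak_invariants():
    iv = GenomicInterval("chr1", 0, 10)
    with pytest.raises(ValidationError):
        ScoredPeak(iv, fdr_tier=5)
    with pytest.raises(ValidationError):
        ScoredPeak(iv, score=float("inf"))
    assert GenomicInterval("chr1", 10, 21).center == 15  # floor((10+21)/2)


def test_merge_intervals_examples():
    ivs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 15),
           GenomicInterval("c", 20, 30)]
    merged = merge_intervals(ivs)
    assert [(m.start, m.end) for m in merged] == [(0, 15), (20, 30)]
    # disjoint input unchanged; abutting not merged
    ivs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20)]
    assert len(merge_intervals(ivs)) == 2


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 9_900), st.integers(1, 100)),
                min_size=0, max_size=100))
def test_merge_matches_positionwise_union_oracle(spans):
    """Merged output must reconstruct the exact per-base union mask."""
    ivs = [GenomicInterval("c", s, s + w) for s, w in spans]
    mask = np.zeros(10_000, dtype=bool)
    for iv in ivs:
        mask[iv.start:iv.end] = True
    merged = merge_intervals(ivs)
    rebuilt = np.zeros(10_000, dtype=bool)
    for prev, cur in zip(merged, merged[1:]):
        assert prev.end < cur.start or prev.end <= cur.start  # sorted, disjoint
    for iv in merged:
        assert not rebuilt[iv.start:iv.end].any()
        rebuilt[iv.start:iv.end] = True
    assert (rebuilt == mask).all()


def test_interval_index_any_overlap():
    idx = IntervalIndex([GenomicInterval("c", 100, 200), GenomicInterval("c", 400, 500)])
    assert idx.any_overlap(GenomicInterval("c", 150, 160))
    assert idx.any_overlap(GenomicInterval("c", 199, 400))  # 1 bp into first
    assert not idx.any_overlap(GenomicInterval("c", 200, 400))  # gap exactly
    assert not idx.any_overlap(GenomicInterval("other", 150, 160))


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------


def test_bed_peak_round_trip(tmp_path):
    peaks = [make_peak("chr2L", 100, 200, score=55.0, name="pk1"),
             make_peak("chr2L", 300, 420, score=12.5, name="pk2"),
             make_peak("chrX", 10, 20, score=0.0, name="pk3")]
    path = tmp_path / "peaks.bed"
    tio.write_bed(peaks, path)
    back = tio.read_bed(path, "peak", factor="Sd", tissue="W", fdr_tier=1)
    assert len(back) == 3
    for a, b in zip(peaks, back):
        assert (a.chrom, a.start, a.end, a.score) == (b.chrom, b.start, b.end, b.score)
        assert a.interval.name == b.interval.name


def test_bed_single_line_maps_fields(tmp_path):
    p = tmp_path / "one.bed"
    p.write_text("chr2L\t100\t200\tpk1\t55\n")
    (peak,) = tio.read_bed(p, "peak")
    assert (peak.chrom, peak.start, peak.end, peak.score) == ("chr2L", 100, 200, 55.0)


def test_bed_empty_and_comments(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("# comment\ntrack name=x\n\n")
    assert tio.read_bed(p) == []
    out = tmp_path / "out.bed"
    tio.write_bed([], out)
    assert out.read_text() == ""


def test_bed_errors_name_line(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr2L\t100\t200\nchr2L\t200\t100\n")
    with pytest.raises(ValidationError, match=":2"):
        tio.read_bed(p)
    p.write_text("chr2L\tten\t200\n")
    with pytest.raises(tio.ParseError, match=":1"):
        tio.read_bed(p)


def test_gene_model_tss_convention(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tx\tmRNA\t1001\t2000\t.\t-\t.\tID=gm\n"
        "chr1\tx\texon\t1001\t2000\t.\t-\t.\tParent=gm\n"
        "chr1\tx\tmRNA\t1001\t2000\t.\t+\t.\tID=gp\n"
        "chr1\tx\texon\t1001\t2000\t.\t+\t.\tParent=gp\n")
    minus, plus = tio.read_gene_models(gff)
    assert (minus.body.start, minus.body.end) == (1000, 2000)
    assert minus.tss == 1999
    assert plus.tss == 1000


def test_gff3_orphan_exon(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text("chr1\tx\texon\t100\t200\t.\t+\t.\tParent=nope\n")
    with pytest.raises(tio.ParseError, match="orphan exon"):
        tio.read_gene_models(gff)


def test_bed12_blocks(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("chr1\t1000\t2000\tg1\t0\t+\t1000\t2000\t0\t2\t100,200\t0,800\n")
    (gene,) = tio.read_gene_models(bed)
    assert len(gene.exons) == 2
    assert (gene.exons[0].start, gene.exons[0].end) == (1000, 1100)
    assert (gene.exons[1].start, gene.exons[1].end) == (1800, 2000)


def test_gff3_round_trip(tmp_path):
    gff = tmp_path / "g.gff3"
    body = GenomicInterval("chr1", 5000, 9000)
    exons = (GenomicInterval("chr1", 5000, 5500), GenomicInterval("chr1", 8000, 9000))
    from tisschip.core import GeneModel
    genes = [GeneModel(gene_id="gA", body=body, strand="-", exons=exons)]
    tio.write_gff3_genes(genes, gff)
    (back,) = tio.read_gene_models(gff)
    assert (back.body.chrom, back.body.start, back.body.end) == ("chr1", 5000, 9000)
    assert back.tss == 8999
    assert [(e.start, e.end) for e in back.exons] == [(5000, 5500), (8000, 9000)]


def test_fasta_round_trip(tmp_path):
    asm = GenomeAssembly(chrom_sizes={"chr1": 10, "chr2": 6},
                         sequence={"chr1": "ACGTACGTAC", "chr2": "TTTAAA"})
    path = tmp_path / "g.fa"
    tio.write_fasta(asm, path)
    back = tio.read_fasta(path)
    assert back.sequence == asm.sequence
    assert back.chrom_sizes == asm.chrom_sizes
    assert back.fetch(GenomicInterval("chr1", 2, 6)) == "GTAC"


def test_bedgraph_round_trip(tmp_path):
    asm = GenomeAssembly(chrom_sizes={"c": 100})
    track = SignalTrack.empty(asm)
    track.values["c"][10:30] = 0.5
    track.values["c"][30:40] = 0.9
    path = tmp_path / "t.bedGraph"
    tio.write_bedgraph(track, path)
    back = tio.read_bedgraph(path, asm)
    assert np.array_equal(back.values["c"], track.values["c"], equal_nan=True)


def test_wiggle_fixed_step(tmp_path):
    asm = GenomeAssembly(chrom_sizes={"c": 20})
    p = tmp_path / "t.wig"
    p.write_text("fixedStep chrom=c start=3 step=1\n0.1\n0.2\n0.3\n")
    track = tio.read_wiggle(p, asm)
    assert np.allclose(track.values["c"][2:5], [0.1, 0.2, 0.3])
    assert np.isnan(track.values["c"][0])


def test_gmt_round_trip(tmp_path):
    from tisschip.core import GeneSetLibrary
    lib = GeneSetLibrary(sets={"s1": frozenset({"a", "b"}), "s2": frozenset({"c"})})
    path = tmp_path / "x.gmt"
    tio.write_gmt(lib, path)
    back = tio.read_gmt(path)
    assert back.sets == lib.sets


def test_enhancer_catalog_round_trip(tmp_path):
    from tisschip.core import EnhancerFragment
    frags = [EnhancerFragment("F1", GenomicInterval("c", 0, 100, name="F1"),
                              {"eye": True, "antenna": False, "leg": False, "wing": True}),
             EnhancerFragment("F2", GenomicInterval("c", 200, 350, name="F2"),
                              {"eye": False, "antenna": False, "leg": True, "wing": False})]
    path = tmp_path / "e.tsv"
    tio.write_enhancer_catalog(frags, path)
    back = tio.read_enhancer_catalog(path)
    assert [(f.id, f.interval.start, f.activity) for f in back] == \
        [(f.id, f.interval.start, dict(f.activity)) for f in frags]
    # duplicate ids rejected
    path.write_text(path.read_text() + "F1\tc\t400\t500\t0\t0\t0\t0\n")
    with pytest.raises(ValidationError, match="duplicate"):
        tio.read_enhancer_catalog(path)


def test_assembly_validates_intervals():
    asm = GenomeAssembly(chrom_sizes={"c": 100})
    with pytest.raises(ValidationError):
        asm.validate_interval(GenomicInterval("c", 50, 150))
    with pytest.raises(ValidationError):
        asm.validate_interval(GenomicInterval("unknown", 0, 10))
    with pytest.raises(ValidationError):
        GenomeAssembly(chrom_sizes={"c": 5}, sequence={"c": "ACGTACGT"})
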