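"""Readers and writers for the plain-text formats the pipeline touches.

BED (3/5/6 columns, native 0-based half-open), GFF3 and BED12 gene models
(GFF3 1-based closed coordinates converted on read), FASTA genomes,
bedGraph and fixed-step wiggle signal tracks, GMT gene-set libraries and
the enhancer-catalog TSV.  Every reader validates against the data-model
invariants and reports the offending line on parse errors.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CHROMATIN_STATES,
    EnhancerFragment,
    GeneModel,
    GeneSetLibrary,
    GenomeAssembly,
    GenomicInterval,
    ScoredPeak,
    Segmentation,
    SignalTrack,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coords(path, lineno, fields):
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated BED columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed coordinate: {exc}") from None
    try:
        return GenomicInterval(chrom, start, end,
                               strand=fields[5] if len(fields) > 5 else ".",
                               name=fields[3] if len(fields) > 3 else "")
    except ValidationError as exc:
        raise ValidationError(f"{path}:{lineno}: {exc}") from None


def read_bed(path, schema: str = "interval", *, factor: str = "",
             tissue: str = "", fdr_tier: int = 1):
    """Read a BED file.

    schema="interval" returns GenomicInterval (BED3/6); schema="peak"
    returns ScoredPeak with the score from column 5 and factor/tissue/tier
    from keyword arguments; schema="segmentation" returns a Segmentation
    with the chromatin-state label taken from the name column.
    Comment/track/browser lines are skipped; input order is preserved.
    """
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        iv = _parse_coords(path, lineno, fields)
        if schema == "interval":
            records.append(iv)
        elif schema == "peak":
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: malformed score {fields[4]!r}") from None
            records.append(ScoredPeak(iv, factor=factor, tissue=tissue,
                                      fdr_tier=fdr_tier, score=score))
        elif schema == "segmentation":
            if iv.name not in CHROMATIN_STATES:
                raise ParseError(f"{path}:{lineno}: unknown chromatin state {iv.name!r}")
            records.append(iv)
        else:
            raise ValueError(f"unknown BED schema {schema!r}")
    if schema == "segmentation":
        return Segmentation(records)
    return records


def write_bed(records: Iterable, path) -> None:
    """Write intervals/peaks as BED; inverse of read_bed field-for-field.

    GenomicInterval -> BED6 (name, 0 score, strand); ScoredPeak -> BED6
    with the enrichment score in column 5.  Segmentation -> BED4 with the
    state label in the name field.
    """
    if isinstance(records, Segmentation):
        records = records.intervals
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ScoredPeak):
                iv = rec.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                         f"\t{rec.score:g}\t{iv.strand}\n")
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name or '.'}"
                         f"\t0\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def _read_gff3_genes(path) -> list[GeneModel]:
    # flat gene/mRNA/exon hierarchy; GFF3 is 1-based closed -> 0-based half-open
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields
        try:
            iv = GenomicInterval(chrom, int(start) - 1, int(end),
                                 strand=strand if strand in "+-" else ".")
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype in ("mRNA", "transcript"):
            tid = attr.get("ID")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: transcript without ID")
            transcripts[tid] = {"body": iv, "strand": strand, "exons": []}
            order.append(tid)
        elif ftype == "exon":
            parent = attr.get("Parent")
            if parent not in transcripts:
                raise ParseError(f"{path}:{lineno}: orphan exon (Parent={parent!r})")
            transcripts[parent]["exons"].append(iv)
    out = []
    for tid in order:
        t = transcripts[tid]
        out.append(GeneModel(gene_id=tid, body=t["body"], strand=t["strand"],
                             exons=tuple(sorted(t["exons"], key=lambda e: e.start))))
    return out


def _read_bed12_genes(path) -> list[GeneModel]:
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"{path}:{lineno}: expected 12 BED12 columns")
        iv = _parse_coords(path, lineno, fields)
        if iv.strand not in "+-":
            raise ParseError(f"{path}:{lineno}: gene model needs a strand")
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != int(fields[9]) or len(offsets) != int(fields[9]):
            raise ParseError(f"{path}:{lineno}: block count mismatch")
        exons = tuple(GenomicInterval(iv.chrom, iv.start + o, iv.start + o + s)
                      for o, s in zip(offsets, sizes))
        out.append(GeneModel(gene_id=iv.name or f"gene{lineno}",
                             body=GenomicInterval(iv.chrom, iv.start, iv.end),
                             strand=iv.strand, exons=exons))
    return out


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3 (``.gff``/``.gff3``) or BED12.

    One GeneModel per transcript; the TSS follows the strand convention
    (body.start on +, body.end-1 on -).
    """
    if str(path).endswith((".gff", ".gff3")):
        return _read_gff3_genes(path)
    return _read_bed12_genes(path)


def write_gff3_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            b = g.body
            fh.write(f"{b.chrom}\ttisschip\tmRNA\t{b.start + 1}\t{b.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for i, ex in enumerate(g.exons, start=1):
                fh.write(f"{ex.chrom}\ttisschip\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_fasta(path, chrom_sizes: dict[str, int] | None = None) -> GenomeAssembly:
    """Load a FASTA genome into a GenomeAssembly with in-memory sequence."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    sizes = chrom_sizes or {name: len(s) for name, s in seqs.items()}
    return GenomeAssembly(chrom_sizes=sizes, sequence=seqs)


def write_fasta(assembly: GenomeAssembly, path, width: int = 80) -> None:
    if assembly.sequence is None:
        raise ValidationError("assembly carries no sequence to write")
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in assembly.sequence.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------


def read_bedgraph(path, assembly: GenomeAssembly) -> SignalTrack:
    """bedGraph -> dense per-base track; uncovered positions stay NaN."""
    track = SignalTrack.empty(assembly)
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        arr = track.values.get(chrom)
        if arr is None:
            raise ParseError(f"{path}:{lineno}: undeclared chromosome {chrom}")
        if not (0 <= start < end <= arr.size):
            raise ParseError(f"{path}:{lineno}: interval outside chromosome")
        arr[start:end] = value
    return track


def write_bedgraph(track: SignalTrack, path, decimals: int = 4) -> None:
    """Write a dense track as run-length-collapsed bedGraph (NaN = gap)."""
    with open(path, "w") as fh:
        for chrom in track.values:
            arr = np.round(track.values[chrom], decimals)
            if arr.size == 0:
                continue
            # run boundaries where the value changes (NaN-aware)
            same = (arr[1:] == arr[:-1]) | (np.isnan(arr[1:]) & np.isnan(arr[:-1]))
            bounds = np.flatnonzero(~same) + 1
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if not np.isnan(v):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_wiggle(path, assembly: GenomeAssembly) -> SignalTrack:
    """Fixed-step wiggle (``fixedStep chrom=... start=... step=...``).

    Wiggle start positions are 1-based; converted to 0-based on read.
    """
    track = SignalTrack.empty(assembly)
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=", 1) for f in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                if chrom not in track.values:
                    raise ParseError(f"{path}:{lineno}: undeclared chromosome {chrom}")
                continue
            if chrom is None:
                raise ParseError(f"{path}:{lineno}: data before fixedStep header")
            value = float(line)
            arr = track.values[chrom]
            if pos + span > arr.size:
                raise ParseError(f"{path}:{lineno}: position outside chromosome")
            arr[pos : pos + span] = value
            pos += step
    return track


# ---------------------------------------------------------------------------
# Gene sets and enhancer catalog
# ---------------------------------------------------------------------------


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetLibrary:
    sets = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT needs name, description, >=1 gene")
        sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    return GeneSetLibrary(sets=sets, universe=frozenset(universe) if universe else None)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for name, members in library.sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(members)) + "\n")


ENHANCER_COLUMNS = ["id", "chrom", "start", "end", "eye", "antenna", "leg", "wing"]


def read_enhancer_catalog(path) -> list[EnhancerFragment]:
    """TSV catalog: id, chrom, start, end, then 0/1 activity per tissue."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ENHANCER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing enhancer-catalog columns {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"{path}: duplicate fragment id {dup!r}")
    out = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end), name=str(row.id))
        activity = {t: bool(int(getattr(row, t))) for t in ("eye", "antenna", "leg", "wing")}
        out.append(EnhancerFragment(id=str(row.id), interval=iv, activity=activity))
    return out


def write_enhancer_catalog(fragments: Sequence[EnhancerFragment], path) -> None:
    rows = [{"id": f.id, "chrom": f.interval.chrom, "start": f.interval.start,
             "end": f.interval.end,
             **{t: int(f.activity[t]) for t in ("eye", "antenna", "leg", "wing")}}
            for f in fragments]
    pd.DataFrame(rows, columns=ENHANCER_COLUMNS).to_csv(path, sep="\t", index=False)
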