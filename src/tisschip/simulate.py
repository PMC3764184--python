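"""Seeded generator for every input the pipeline consumes.

The generator emits a complete file bundle (genome FASTA, chromosome
sizes, GFF3 gene models, per-factor/tissue/tier peak BEDs, five-state
segmentation BED, conservation bedGraph, ultraconserved-element BED,
enhancer-catalog TSV, GMT gene sets) plus a ground-truth manifest, and is
byte-deterministic in the master seed.  The default configuration mimics
the statistical regime of tiling-array ChIP in two imaginal discs for
three factors: a wing-rich asymmetry in tissue-specific calls (~2000
wing-specific vs ~150 eye-specific for the two DNA-binding factors),
nested FDR tiers, a 46% promoter share for tissue-shared events,
Polycomb-state (BLUE) bias for tissue-specific events, state-dependent
motif-containment rates (0.51 in BLUE vs 0.37 in YELLOW), and elevated
conservation/ultraconservation at a subset of specific peaks.

Placement uses one occupancy bitmap per factor so that, within a factor,
no two emitted intervals of any tier overlap except the deliberately
shared cross-tissue pairs — which makes the shared/specific ground truth
exact rather than approximate.  Peaks not designated as promoter peaks
reject positions inside any promoter window, so the planted promoter
share is exact as well.  Motif content is controlled per peak: a Bernoulli
flag decides whether the peak contains the factor's motif, flagged peaks
get one occurrence planted near the centre, and unflagged peaks are
scrubbed (matches mutated away, avoiding planted sites of other factors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as tio
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
from .core import IntervalIndex
from .motifs import IUPAC, IUPACPattern, scan
from .specificity import DualTierPeakSet, classify

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_n_peaks():
    # FDR1 counts per factor and tissue; W-rich asymmetry for Sd and Hth
    return {
        "Yki": {"EA": 2500, "W": 2540},
        "Sd": {"EA": 1350, "W": 3200},
        "Hth": {"EA": 1350, "W": 3200},
    }


def _default_shared_fraction():
    # fraction of the tissue-b (W) FDR1 peaks that are tissue-shared
    return {"Yki": 0.945, "Sd": 0.375, "Hth": 0.375}


def _default_state_shares():
    return {"YELLOW": 0.20, "RED": 0.15, "BLUE": 0.15, "GREEN": 0.15, "BLACK": 0.35}


def _default_state_bias():
    return {
        "shared": {"YELLOW": 0.60, "RED": 0.20, "BLUE": 0.10, "GREEN": 0.05, "BLACK": 0.05},
        "specific": {"YELLOW": 0.18, "RED": 0.25, "BLUE": 0.32, "GREEN": 0.10, "BLACK": 0.15},
    }


def _default_motif_patterns():
    return {"Sd": "GGAATG", "Hth": "TGAY[N0-2]TGAY"}


def _default_motif_rates():
    # probability a peak contains the factor's motif, by chromatin state
    return {"YELLOW": 0.37, "RED": 0.45, "BLUE": 0.51, "GREEN": 0.40, "BLACK": 0.40}


def _default_promoter_fraction():
    return {"shared": 0.46, "specific": 0.08}


def _default_uce_rate():
    return {"shared": 0.05, "specific": 0.30}


def _default_conserved_rate():
    return {"shared": 0.15, "specific": 0.50}


def _default_activity_base():
    return {"eye": 0.25, "antenna": 0.20, "leg": 0.20, "wing": 0.30}


def _default_activity_given_binding():
    # reporter-activity probability per tissue given the fragment overlaps
    # a peak of the named class ("specific_b" = wing-specific by default)
    return {
        "specific_b": {"wing": 0.90, "eye": 0.50},
        "specific_a": {"eye": 0.85, "wing": 0.55},
        "shared": {"wing": 0.60, "eye": 0.60},
    }


@dataclass
class GeneratorConfig:
    """Stated world of the fig-mimic scenario; the seed fixes every byte."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 2_500_000
    factors: tuple[str, ...] = ("Yki", "Sd", "Hth")
    tissue_a: str = "EA"
    tissue_b: str = "W"
    n_peaks: dict = field(default_factory=_default_n_peaks)
    shared_fraction: dict = field(default_factory=_default_shared_fraction)
    fdr25_inflation: float = 0.5
    fdr1_halfwidth: int = 150
    fdr25_pad: int = 100
    decoy_halfwidth: int = 200
    site_spacing: int = 700
    state_genome_shares: dict = field(default_factory=_default_state_shares)
    mean_segment_length: int = 5000
    state_bias: dict = field(default_factory=_default_state_bias)
    promoter_fraction: dict = field(default_factory=_default_promoter_fraction)
    promoter_window: int = 1000
    motif_patterns: dict = field(default_factory=_default_motif_patterns)
    motif_rates: dict = field(default_factory=_default_motif_rates)
    motif_center_sd: float = 40.0
    conservation_inside: float = 0.9
    conservation_outside: float = 0.1
    conserved_rate: dict = field(default_factory=_default_conserved_rate)
    uce_rate: dict = field(default_factory=_default_uce_rate)
    uce_length: int = 60
    n_genes: int = 1200
    gene_length_range: tuple[int, int] = (1500, 4000)
    max_exons: int = 4
    n_enhancers: int = 600
    enhancer_length_range: tuple[int, int] = (1000, 3000)
    enhancer_on_peak_fraction: float = 0.4
    activity_base: dict = field(default_factory=_default_activity_base)
    activity_given_binding: dict = field(default_factory=_default_activity_given_binding)
    n_gene_sets: int = 20
    gene_set_size: int = 50
    planted_set_size: int = 60

    def validate(self) -> None:
        for name, frac in [("shared_fraction", self.shared_fraction.values()),
                           ("promoter_fraction", self.promoter_fraction.values()),
                           ("motif_rates", self.motif_rates.values()),
                           ("uce_rate", self.uce_rate.values()),
                           ("conserved_rate", self.conserved_rate.values())]:
            for v in frac:
                if not 0 <= v <= 1:
                    raise ValidationError(f"{name} value {v} outside [0, 1]")
        if abs(sum(self.state_genome_shares.values()) - 1) > 1e-9:
            raise ValidationError("state_genome_shares must sum to 1")
        genome = self.n_chroms * self.chrom_length
        for f in self.factors:
            n_b = self.n_peaks[f][self.tissue_b]
            n_a = self.n_peaks[f][self.tissue_a]
            n_shared = round(self.shared_fraction[f] * n_b)
            if n_shared > n_a:
                raise ValidationError(
                    f"{f}: shared count {n_shared} exceeds {self.tissue_a} FDR1 count {n_a}")
            n_sites = n_a + n_b - n_shared
            n_sites += round(self.fdr25_inflation * n_a) + round(self.fdr25_inflation * n_b)
            if n_sites * self.site_spacing > 0.7 * genome:
                raise ValidationError(
                    f"{f}: {n_sites} sites x {self.site_spacing} bp spacing exceeds "
                    f"70% of the {genome} bp genome; enlarge the genome or thin the peaks")


# ---------------------------------------------------------------------------
# Internal placement helpers
# ---------------------------------------------------------------------------


class _Layout:
    def __init__(self, cfg: GeneratorConfig):
        self.chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
        self.sizes = {c: cfg.chrom_length for c in self.chroms}
        self.offsets = np.arange(cfg.n_chroms) * cfg.chrom_length
        self.total = cfg.n_chroms * cfg.chrom_length
        self.chrom_length = cfg.chrom_length

    def to_local(self, g: int) -> tuple[str, int]:
        i = int(g) // self.chrom_length
        return self.chroms[i], int(g) - i * self.chrom_length

    def to_global(self, chrom: str, pos: int) -> int:
        return self.chroms.index(chrom) * self.chrom_length + pos

    def in_margin(self, g: int, margin: int) -> bool:
        pos = int(g) % self.chrom_length
        return margin <= pos < self.chrom_length - margin


class _Bitmap:
    """Coarse occupancy map (50 bp cells) over the linearised genome."""

    CELL = 50

    def __init__(self, total: int):
        self.cells = np.zeros(total // self.CELL + 2, dtype=bool)

    def free(self, g: int, radius: int) -> bool:
        return self.free_range(g - radius, g + radius)

    def mark(self, g: int, radius: int) -> None:
        self.mark_range(g - radius, g + radius)

    def free_range(self, lo: int, hi: int) -> bool:
        return not self.cells[max(lo, 0) // self.CELL : hi // self.CELL + 1].any()

    def mark_range(self, lo: int, hi: int) -> None:
        self.cells[max(lo, 0) // self.CELL : hi // self.CELL + 1] = True


class _StateSampler:
    """Draw genome positions whose centre lies in a segment of a given state."""

    def __init__(self, segments: list[tuple[int, int, str]]):
        self.by_state = {}
        for state in CHROMATIN_STATES:
            segs = [(s, e) for s, e, lab in segments if lab == state]
            starts = np.asarray([s for s, _ in segs])
            lens = np.asarray([e - s for s, e in segs])
            self.by_state[state] = (starts, lens, np.concatenate([[0], np.cumsum(lens)]))

    def draw(self, state: str, rng: np.random.Generator) -> int:
        starts, lens, cum = self.by_state[state]
        if cum[-1] == 0:
            raise ValidationError(f"no segments of state {state}")
        u = int(rng.integers(cum[-1]))
        i = int(np.searchsorted(cum, u, side="right")) - 1
        return int(starts[i] + (u - cum[i]))


def _place(attempts, propose, accept):
    for _ in range(attempts):
        g = propose()
        if accept(g):
            return g
    raise ValidationError("placement failed: genome too crowded for the requested intervals")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "fasta": "genome.fa",
    "chrom_sizes": "chrom.sizes",
    "genes": "genes.gff3",
    "segmentation": "segmentation.bed",
    "conservation": "conservation.bedGraph",
    "uces": "uces.bed",
    "enhancers": "enhancers.tsv",
    "gene_sets": "gene_sets.gmt",
    "manifest": "manifest.json",
}


def peak_file_name(factor: str, tissue: str, tier: int) -> str:
    return f"{factor}_{tissue}_fdr{tier}.bed"


def generate(config: GeneratorConfig, out_dir) -> dict:
    """Write the full synthetic bundle to ``out_dir``; returns the manifest."""
    cfg = config
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    streams = {name: np.random.default_rng([cfg.seed, k]) for k, name in enumerate(
        ["segmentation", "genes", "peaks", "sequence", "motifs", "scrub",
         "conservation", "enhancers", "gene_sets", "scores"])}
    layout = _Layout(cfg)

    # --- five-state segmentation -----------------------------------------
    rng = streams["segmentation"]
    states = list(CHROMATIN_STATES)
    spans: list[tuple[str, int, int]] = []  # (chrom, start, end)
    for chrom in layout.chroms:
        pos = 0
        while pos < cfg.chrom_length:
            length = int(rng.exponential(cfg.mean_segment_length)) + 500
            end = min(pos + length, cfg.chrom_length)
            spans.append((chrom, pos, end))
            pos = end
    # labels fill per-state length quotas (greedy, in random order) so the
    # realized genome shares match the stated shares to within one segment
    deficits = {s: cfg.state_genome_shares[s] * layout.total for s in states}
    labels = [None] * len(spans)
    for i in rng.permutation(len(spans)):
        chrom, s, e = spans[i]
        label = max(states, key=lambda st: deficits[st])
        deficits[label] -= e - s
        labels[i] = label
    segments = [(layout.to_global(chrom, s), layout.to_global(chrom, e), lab)
                for (chrom, s, e), lab in zip(spans, labels)]
    seg_intervals = [GenomicInterval(chrom, s, e, name=lab)
                     for (chrom, s, e), lab in zip(spans, labels)]
    segmentation = Segmentation(seg_intervals)
    sampler = _StateSampler(segments)

    # --- gene models ------------------------------------------------------
    rng = streams["genes"]
    gene_bitmap = _Bitmap(layout.total)
    promoter_mask = np.zeros(layout.total, dtype=bool)
    genes: list[GeneModel] = []
    lo_len, hi_len = cfg.gene_length_range
    for gi in range(cfg.n_genes):
        length = int(rng.integers(lo_len, hi_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        # reserve the body plus the strand-aware upstream promoter window
        up = cfg.promoter_window + 200 if strand == "+" else 200
        down = 200 if strand == "+" else cfg.promoter_window + 200
        half = length // 2
        reserve = half + cfg.promoter_window + 400

        def _propose():
            return int(rng.integers(reserve + 200, layout.total - reserve - 200))

        g = _place(400, _propose,
                   lambda g: layout.in_margin(g, reserve + 100)
                   and gene_bitmap.free_range(g - half - up, g + half + down))
        gene_bitmap.mark_range(g - half - up, g + half + down)
        chrom, center = layout.to_local(g)
        start = center - length // 2
        body = GenomicInterval(chrom, start, start + length)
        n_ex = int(rng.integers(1, cfg.max_exons + 1))
        if n_ex == 1:
            exons = (body,)
        else:
            cuts = np.sort(rng.choice(np.arange(start + 100, start + length - 100, 50),
                                      size=2 * n_ex - 2, replace=False))
            bounds = [start, *cuts.tolist(), start + length]
            exons = tuple(GenomicInterval(chrom, bounds[i], bounds[i + 1])
                          for i in range(0, len(bounds) - 1, 2))
        gene = GeneModel(gene_id=f"g{gi:04d}", body=body, strand=strand, exons=exons)
        genes.append(gene)
        tss_g = layout.to_global(chrom, gene.tss)
        if strand == "+":
            promoter_mask[tss_g - cfg.promoter_window : tss_g] = True
        else:
            promoter_mask[tss_g + 1 : tss_g + cfg.promoter_window + 1] = True

    # --- peak placement ---------------------------------------------------
    rng = streams["peaks"]
    hw1, pad = cfg.fdr1_halfwidth, cfg.fdr25_pad
    reserve = cfg.site_spacing // 2
    peak_records: list[dict] = []
    decoys: dict[tuple[str, str], list[tuple[int, int]]] = {}
    genes_by_strand = {"+": [g for g in genes if g.strand == "+"],
                       "-": [g for g in genes if g.strand == "-"]}

    for factor in cfg.factors:
        bitmap = _Bitmap(layout.total)
        n_b = cfg.n_peaks[factor][cfg.tissue_b]
        n_a = cfg.n_peaks[factor][cfg.tissue_a]
        n_shared = round(cfg.shared_fraction[factor] * n_b)
        classes = ([("shared", None)] * n_shared
                   + [("specific", cfg.tissue_b)] * (n_b - n_shared)
                   + [("specific", cfg.tissue_a)] * (n_a - n_shared))
        # per-factor gene pool for promoter placements, sampled w/o replacement
        gene_pool = list(rng.permutation(len(genes)))
        bias = cfg.state_bias
        for cls, tissue in classes:
            at_promoter = rng.random() < cfg.promoter_fraction[cls]
            gene_id = None
            if at_promoter:
                center_g = None
                while gene_pool and center_g is None:
                    gene = genes[gene_pool.pop()]
                    tss_g = layout.to_global(gene.chrom, gene.tss)
                    for _ in range(20):
                        d = int(rng.integers(100, cfg.promoter_window - 99))
                        g = tss_g - d if gene.strand == "+" else tss_g + d
                        if layout.in_margin(g, reserve + 100) and bitmap.free(g, reserve):
                            center_g, gene_id = g, gene.gene_id
                            break
                if center_g is None:
                    raise ValidationError(f"{factor}: ran out of promoter slots")
            else:
                state_names = list(bias[cls])
                p = np.asarray([bias[cls][s] for s in state_names])
                target = state_names[int(rng.choice(len(state_names), p=p))]
                center_g = _place(
                    500, lambda: sampler.draw(target, rng),
                    lambda g: layout.in_margin(g, reserve + 100)
                    and bitmap.free(g, reserve) and not promoter_mask[g])
            bitmap.mark(center_g, reserve)
            chrom, c = layout.to_local(center_g)
            peak_records.append({
                "factor": factor, "class": cls, "tissue": tissue,
                "chrom": chrom, "start": c - hw1, "end": c + hw1,
                "center_g": int(center_g),
                "state": segmentation.label_at(chrom, c),
                "promoter": bool(at_promoter), "gene_id": gene_id,
            })
        for tissue, n_t in ((cfg.tissue_a, n_a), (cfg.tissue_b, n_b)):
            n_decoy = round(cfg.fdr25_inflation * n_t)
            lst = []
            dhw = cfg.decoy_halfwidth
            for _ in range(n_decoy):
                g = _place(500,
                           lambda: int(rng.integers(reserve, layout.total - reserve)),
                           lambda g: layout.in_margin(g, reserve + 100)
                           and bitmap.free(g, reserve))
                bitmap.mark(g, reserve)
                lst.append((g - dhw, g + dhw))
            decoys[(factor, tissue)] = lst

    # --- genome sequence with controlled motif content --------------------
    genome_codes = streams["sequence"].integers(0, 4, size=layout.total, dtype=np.uint8)
    rng = streams["motifs"]
    patterns = {f: IUPACPattern.parse(p, name=f"{f}_motif")
                for f, p in cfg.motif_patterns.items()}
    planted: list[tuple[int, int]] = []  # global extents of planted sites
    planted_mask = np.zeros(layout.total, dtype=bool)

    def _realize(pattern: IUPACPattern) -> str:
        symbols = pattern.expansions()[int(rng.integers(len(pattern.expansions())))]
        return "".join(IUPAC[s][int(rng.integers(len(IUPAC[s])))] for s in symbols)

    for rec in peak_records:
        pat = patterns.get(rec["factor"])
        if pat is None:
            rec["motif"] = None
            continue
        rec["motif"] = bool(rng.random() < cfg.motif_rates[rec["state"]])
        if rec["motif"]:
            site = _realize(pat)
            lo = layout.to_global(rec["chrom"], rec["start"]) + 5
            hi = layout.to_global(rec["chrom"], rec["end"]) - 5 - len(site)
            center = (lo + hi) // 2
            # keep plants of overlapping peaks (other factors) intact
            for _ in range(50):
                pos = int(np.clip(round(rng.normal(center, cfg.motif_center_sd)), lo, hi))
                if not planted_mask[pos : pos + len(site)].any():
                    break
            else:
                raise ValidationError("could not place a motif site clear of other plants")
            genome_codes[pos : pos + len(site)] = ["ACGT".index(ch) for ch in site]
            planted.append((pos, pos + len(site)))
            planted_mask[pos : pos + len(site)] = True

    _scrub_negatives(cfg, layout, genome_codes, peak_records, patterns,
                     planted, streams["scrub"])

    decode = bytes.maketrans(bytes(range(4)), b"ACGT")
    assembly = GenomeAssembly(
        chrom_sizes=dict(layout.sizes),
        sequence={c: genome_codes[layout.offsets[i]: layout.offsets[i] + cfg.chrom_length]
                  .tobytes().translate(decode).decode()
                  for i, c in enumerate(layout.chroms)})

    # --- conservation track and UCEs --------------------------------------
    rng = streams["conservation"]
    cons = np.full(layout.total, cfg.conservation_outside)
    uces: list[GenomicInterval] = []
    for rec in peak_records:
        rec["conserved"] = bool(rng.random() < cfg.conserved_rate[rec["class"]])
        if rec["conserved"]:
            s = layout.to_global(rec["chrom"], rec["start"])
            cons[s : s + (rec["end"] - rec["start"])] = cfg.conservation_inside
        rec["uce"] = bool(rng.random() < cfg.uce_rate[rec["class"]])
        if rec["uce"]:
            c = rec["center_g"]
            chrom, pos = layout.to_local(c)
            uces.append(GenomicInterval(chrom, pos - cfg.uce_length // 2,
                                        pos - cfg.uce_length // 2 + cfg.uce_length))
    track = SignalTrack({c: cons[layout.offsets[i]: layout.offsets[i] + cfg.chrom_length]
                         .copy() for i, c in enumerate(layout.chroms)})
    uces.sort()

    # --- enhancer catalog --------------------------------------------------
    rng = streams["enhancers"]
    lo_e, hi_e = cfg.enhancer_length_range
    frag_records = []
    class_index = _build_class_index(cfg, layout, peak_records)
    for fi in range(cfg.n_enhancers):
        length = int(rng.integers(lo_e, hi_e + 1))
        if rng.random() < cfg.enhancer_on_peak_fraction and peak_records:
            anchor = peak_records[int(rng.integers(len(peak_records)))]
            g = anchor["center_g"] + int(rng.integers(-length // 3, length // 3 + 1))
        else:
            g = int(rng.integers(length, layout.total - length))
        chrom, center = layout.to_local(g)
        start = int(np.clip(center - length // 2, 0, cfg.chrom_length - length))
        iv = GenomicInterval(chrom, start, start + length, name=f"F{fi:04d}")
        bound = _bound_classes(cfg, layout, class_index, iv)
        activity = {}
        for tissue in ("eye", "antenna", "leg", "wing"):
            p = cfg.activity_base[tissue]
            for cls in bound:
                p = max(p, cfg.activity_given_binding.get(cls, {}).get(tissue, 0.0))
            activity[tissue] = bool(rng.random() < p)
        frag_records.append({"id": iv.name, "interval": iv, "bound_classes": sorted(bound),
                             "activity": activity})
    fragments = [EnhancerFragment(id=f["id"], interval=f["interval"],
                                  activity=f["activity"]) for f in frag_records]

    # --- gene-set library ---------------------------------------------------
    rng = streams["gene_sets"]
    universe = [g.gene_id for g in genes]
    sets: dict[str, frozenset] = {}
    specific_target_genes = sorted({r["gene_id"] for r in peak_records
                                    if r["gene_id"] and r["class"] == "specific"})
    if specific_target_genes:
        k = min(cfg.planted_set_size, len(specific_target_genes))
        members = list(rng.choice(specific_target_genes, size=k, replace=False))
        sets["tissue_program_planted"] = frozenset(members)
    for si in range(cfg.n_gene_sets):
        members = rng.choice(universe, size=cfg.gene_set_size, replace=False)
        sets[f"SET_{si:03d}"] = frozenset(members.tolist())
    library = GeneSetLibrary(sets=sets, universe=frozenset(universe))

    # --- peak files and scores ---------------------------------------------
    rng = streams["scores"]
    peak_sets: dict[tuple[str, str, int], list[ScoredPeak]] = {}
    for factor in cfg.factors:
        for tissue in (cfg.tissue_a, cfg.tissue_b):
            peak_sets[(factor, tissue, 1)] = []
            peak_sets[(factor, tissue, 25)] = []
    for i, rec in enumerate(peak_records):
        tissues = ([cfg.tissue_a, cfg.tissue_b] if rec["class"] == "shared"
                   else [rec["tissue"]])
        score = float(np.round(max(rng.normal(8.0, 2.0), 1.0), 3))
        for tissue in tissues:
            name = f"{rec['factor']}_{tissue}_{i:05d}"
            iv1 = GenomicInterval(rec["chrom"], rec["start"], rec["end"], name=name)
            iv25 = GenomicInterval(rec["chrom"], rec["start"] - pad,
                                   rec["end"] + pad, name=name)
            peak_sets[(rec["factor"], tissue, 1)].append(
                ScoredPeak(iv1, factor=rec["factor"], tissue=tissue, fdr_tier=1, score=score))
            peak_sets[(rec["factor"], tissue, 25)].append(
                ScoredPeak(iv25, factor=rec["factor"], tissue=tissue, fdr_tier=25,
                           score=score))
    for (factor, tissue), lst in decoys.items():
        for j, (gs, ge) in enumerate(lst):
            chrom, s = layout.to_local(gs)
            iv = GenomicInterval(chrom, s, s + (ge - gs), name=f"{factor}_{tissue}_d{j:05d}")
            score = float(np.round(max(rng.normal(3.0, 1.0), 0.1), 3))
            peak_sets[(factor, tissue, 25)].append(
                ScoredPeak(iv, factor=factor, tissue=tissue, fdr_tier=25, score=score))
    for key in peak_sets:
        peak_sets[key].sort(key=lambda p: (p.chrom, p.start))

    # --- ground truth for gene regulatory-logic classes ---------------------
    gene_logic = _gene_logic_truth(cfg, peak_records, genes)

    # --- write bundle --------------------------------------------------------
    tio.write_fasta(assembly, out / BUNDLE_FILES["fasta"])
    tio.write_chrom_sizes(layout.sizes, out / BUNDLE_FILES["chrom_sizes"])
    tio.write_gff3_genes(genes, out / BUNDLE_FILES["genes"])
    tio.write_bed(segmentation, out / BUNDLE_FILES["segmentation"])
    tio.write_bedgraph(track, out / BUNDLE_FILES["conservation"])
    tio.write_bed(uces, out / BUNDLE_FILES["uces"])
    tio.write_enhancer_catalog(fragments, out / BUNDLE_FILES["enhancers"])
    tio.write_gmt(library, out / BUNDLE_FILES["gene_sets"])
    for (factor, tissue, tier), peaks in peak_sets.items():
        tio.write_bed(peaks, out / peak_file_name(factor, tissue, tier))

    manifest = {
        "config": _jsonable(asdict(cfg)),
        "chrom_sizes": dict(layout.sizes),
        "peaks": [{k: v for k, v in rec.items() if k != "center_g"}
                  for rec in peak_records],
        "decoy_counts": {f"{f}/{t}": len(lst) for (f, t), lst in decoys.items()},
        "gene_logic": gene_logic,
        "fragments": [{"id": f["id"], "bound_classes": f["bound_classes"],
                       "activity": {k: bool(v) for k, v in f["activity"].items()}}
                      for f in frag_records],
        "summary": _summary(cfg, peak_records),
    }
    with open(out / BUNDLE_FILES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    return x


def _summary(cfg, peak_records):
    out = {}
    for factor in cfg.factors:
        recs = [r for r in peak_records if r["factor"] == factor]
        shared = sum(1 for r in recs if r["class"] == "shared")
        out[factor] = {
            "shared": shared,
            f"specific_{cfg.tissue_a}": sum(1 for r in recs if r["class"] == "specific"
                                            and r["tissue"] == cfg.tissue_a),
            f"specific_{cfg.tissue_b}": sum(1 for r in recs if r["class"] == "specific"
                                            and r["tissue"] == cfg.tissue_b),
        }
    return out


def _scrub_negatives(cfg, layout, genome_codes, peak_records, patterns, planted, rng):
    """Mutate away motif matches in peaks flagged motif-free.

    Avoids touching planted sites of any factor; repeats up to 3 rounds so
    scrub mutations or cross-factor plants cannot silently re-create
    matches.
    """
    decode = bytes.maketrans(bytes(range(4)), b"ACGT")
    planted_starts = None
    for _ in range(3):
        planted_sorted = sorted(planted)
        planted_starts = np.asarray([s for s, _ in planted_sorted])
        planted_ends = np.asarray([e for _, e in planted_sorted])
        dirty = 0
        for rec in peak_records:
            if rec.get("motif") is not False:
                continue
            pat = patterns[rec["factor"]]
            gs = layout.to_global(rec["chrom"], rec["start"])
            ge = gs + (rec["end"] - rec["start"])
            for _attempt in range(50):
                seq = genome_codes[gs:ge].tobytes().translate(decode).decode()
                matches = scan(seq, pat)
                if not matches:
                    break
                mutated = False
                for m in matches:
                    for j in range(m.start, m.end):
                        gpos = gs + j
                        i = int(np.searchsorted(planted_starts, gpos, side="right")) - 1
                        inside_plant = i >= 0 and gpos < planted_ends[i]
                        if not inside_plant:
                            old = genome_codes[gpos]
                            new = (old + 1 + int(rng.integers(3))) % 4
                            genome_codes[gpos] = new
                            mutated = True
                            break
                    if mutated:
                        break
                if not mutated:
                    break  # every match position sits in another plant; accept
            else:
                dirty += 1
        if dirty == 0:
            break


def _build_class_index(cfg, layout, peak_records):
    index: dict[str, list[GenomicInterval]] = {}
    for rec in peak_records:
        if rec["class"] == "shared":
            cls = "shared"
        else:
            cls = "specific_b" if rec["tissue"] == cfg.tissue_b else "specific_a"
        index.setdefault(cls, []).append(
            GenomicInterval(rec["chrom"], rec["start"], rec["end"]))
    return {cls: IntervalIndex(ivs) for cls, ivs in index.items()}


def _bound_classes(cfg, layout, class_index, iv: GenomicInterval) -> set[str]:
    return {cls for cls, idx in class_index.items() if idx.any_overlap(iv)}


def _gene_logic_truth(cfg, peak_records, genes, max_distance: int = 10000):
    """Per-factor gene logic classes from the generator's own peak truth."""
    out = {}
    for factor in cfg.factors:
        recs = [r for r in peak_records if r["factor"] == factor]
        by_chrom: dict[str, list[dict]] = {}
        for r in recs:
            by_chrom.setdefault(r["chrom"], []).append(r)
        gene_classes = {}
        for gene in genes:
            labels = set()
            for r in by_chrom.get(gene.chrom, []):
                hits_body = r["start"] < gene.body.end and gene.body.start < r["end"]
                near_tss = r["start"] - max_distance <= gene.tss < r["end"] + max_distance
                if hits_body or near_tss:
                    labels.add(r["class"])
            if labels == {"shared"}:
                gene_classes[gene.gene_id] = "SHARED_ONLY"
            elif labels == {"specific"}:
                gene_classes[gene.gene_id] = "SPECIFIC_ONLY"
            elif labels:
                gene_classes[gene.gene_id] = "SHARED_PLUS_SPECIFIC"
        out[factor] = gene_classes
    return out


# ---------------------------------------------------------------------------
# Bundle loading and manifest validation
# ---------------------------------------------------------------------------


@dataclass
class Bundle:
    """A generated bundle loaded back into memory."""

    assembly: GenomeAssembly
    genes: list[GeneModel]
    segmentation: Segmentation
    conservation: SignalTrack
    uces: list[GenomicInterval]
    fragments: list[EnhancerFragment]
    library: GeneSetLibrary
    peak_sets: dict  # (factor, tissue) -> DualTierPeakSet
    manifest: dict


def load_bundle(bundle_dir) -> Bundle:
    d = Path(bundle_dir)
    with open(d / BUNDLE_FILES["manifest"]) as fh:
        manifest = json.load(fh)
    sizes = tio.read_chrom_sizes(d / BUNDLE_FILES["chrom_sizes"])
    assembly = tio.read_fasta(d / BUNDLE_FILES["fasta"], chrom_sizes=sizes)
    cfg = manifest["config"]
    peak_sets = {}
    for factor in cfg["factors"]:
        for tissue in (cfg["tissue_a"], cfg["tissue_b"]):
            fdr1 = tio.read_bed(d / peak_file_name(factor, tissue, 1), "peak",
                                factor=factor, tissue=tissue, fdr_tier=1)
            fdr25 = tio.read_bed(d / peak_file_name(factor, tissue, 25), "peak",
                                 factor=factor, tissue=tissue, fdr_tier=25)
            peak_sets[(factor, tissue)] = DualTierPeakSet(
                factor=factor, tissue=tissue, fdr1_peaks=fdr1, fdr25_peaks=fdr25)
    return Bundle(
        assembly=assembly,
        genes=tio.read_gene_models(d / BUNDLE_FILES["genes"]),
        segmentation=tio.read_bed(d / BUNDLE_FILES["segmentation"], "segmentation"),
        conservation=tio.read_bedgraph(d / BUNDLE_FILES["conservation"], assembly),
        uces=tio.read_bed(d / BUNDLE_FILES["uces"]),
        fragments=tio.read_enhancer_catalog(d / BUNDLE_FILES["enhancers"]),
        library=tio.read_gmt(d / BUNDLE_FILES["gene_sets"]),
        peak_sets=peak_sets,
        manifest=manifest,
    )


@dataclass
class ValidationReport:
    passed: bool
    n_checked: int
    failures: list[str]


def validate_manifest(bundle_dir, max_failures: int = 20) -> ValidationReport:
    """Re-verify every manifest claim from the emitted files.

    Checks threshold nesting, shared/specific labels against a fresh
    classification, chromatin-state and promoter claims, planted-motif
    claims by re-scanning the genome, and UCE claims.  Stops collecting
    after ``max_failures`` failures.
    """
    failures: list[str] = []
    n_checked = 0
    try:
        bundle = load_bundle(bundle_dir)
    except ValidationError as exc:  # e.g. tampered nesting
        return ValidationReport(False, 1, [f"bundle load failed: {exc}"])
    manifest = bundle.manifest
    cfg = manifest["config"]
    patterns = {f: IUPACPattern.parse(p) for f, p in cfg["motif_patterns"].items()}

    labels: dict[tuple, str] = {}
    for factor in cfg["factors"]:
        result = classify(bundle.peak_sets[(factor, cfg["tissue_a"])],
                          bundle.peak_sets[(factor, cfg["tissue_b"])])
        for tissue, calls in result.calls.items():
            for c in calls:
                labels[(factor, tissue, c.peak.chrom, c.peak.start)] = c.label.value

    from .core import IntervalIndex
    uce_index = IntervalIndex(bundle.uces)
    for rec in manifest["peaks"]:
        if len(failures) >= max_failures:
            failures.append("... further failures suppressed")
            break
        n_checked += 1
        where = f"{rec['factor']} {rec['chrom']}:{rec['start']}-{rec['end']}"
        tissues = ([cfg["tissue_a"], cfg["tissue_b"]] if rec["class"] == "shared"
                   else [rec["tissue"]])
        want = "SHARED" if rec["class"] == "shared" else "SPECIFIC"
        for tissue in tissues:
            got = labels.get((rec["factor"], tissue, rec["chrom"], rec["start"]))
            if got != want:
                failures.append(f"{where}: classification {got} != manifest {want}")
        iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"])
        state = bundle.segmentation.label_at(rec["chrom"], iv.center)
        if state != rec["state"]:
            failures.append(f"{where}: state {state} != manifest {rec['state']}")
        if rec.get("motif") is not None:
            pat = patterns[rec["factor"]]
            found = bool(scan(bundle.assembly.fetch(iv), pat))
            if found != rec["motif"]:
                failures.append(f"{where}: motif presence {found} != manifest {rec['motif']}")
        if rec["uce"] and not uce_index.any_overlap(iv):
            failures.append(f"{where}: manifest claims a UCE but none overlaps")
        if rec["promoter"]:
            gene = next((g for g in bundle.genes if g.gene_id == rec["gene_id"]), None)
            if gene is None:
                failures.append(f"{where}: promoter peak references unknown gene")
            else:
                pos = iv.center
                ok = (gene.tss - cfg["promoter_window"] <= pos < gene.tss
                      if gene.strand == "+"
                      else gene.tss < pos <= gene.tss + cfg["promoter_window"])
                if not ok:
                    failures.append(f"{where}: centre not in promoter of {rec['gene_id']}")
    return ValidationReport(passed=not failures, n_checked=n_checked, failures=failures)
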