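"""End-to-end orchestration: classify, then characterise each class.

Stages run in dependency order (classification -> co-occurrence matrices
-> region breakdown -> target-gene logic partition and gene-set
enrichment -> motif statistics -> conservation/chromatin context ->
enhancer-catalog summary).  Stages whose optional inputs are absent are
skipped with an explicit notice in the run report, never silently.  A
rerun on the same inputs and configuration is byte-identical: the
pipeline draws no randomness and all outputs use fixed formatting.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as tio
from .annotation import assign_targets, gene_set_enrichment, region_breakdown
from .context import (
    profile_scores,
    state_enrichment,
    state_enrichment_table,
    uce_overlap_fraction,
)
from .core import GenomeAssembly, GenomicInterval, ScoredPeak, ValidationError
from .motifs import IUPACPattern, MotifLibrary, central_enrichment, compare_fractions, peak_motif_fraction
from .overlap import pairwise_matrix, summarize_enhancer_overlap
from .simulate import BUNDLE_FILES, peak_file_name
from .specificity import DualTierPeakSet, Label, classify, shared_consensus

log = logging.getLogger("tisschip")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Inputs and parameters of a full pipeline run.

    Defaults that mirror the published thresholds (FDR tiers 1/25, 1 kb
    promoter window, +/-500 bp profile, E-value threshold 10) are exposed
    here rather than hard-coded in the stages.
    """

    out_dir: str
    factors: list[str]
    tissue_a: str
    tissue_b: str
    peak_paths: dict  # factor -> tissue -> {"fdr1": path, "fdr25": path}
    chrom_sizes: str
    fasta: str | None = None
    genes: str | None = None
    segmentation: str | None = None
    conservation: str | None = None
    uces: str | None = None
    enhancers: str | None = None
    gene_sets: str | None = None
    motif_patterns: dict = field(default_factory=dict)  # factor -> pattern text
    bin_width: int = 1000
    promoter_window: int = 1000
    target_max_distance: int = 10000
    profile_halfwidth: int = 500
    e_value_threshold: float = 10.0
    central_window: int = 300
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    @classmethod
    def from_bundle(cls, bundle_dir, out_dir, **overrides) -> "RunConfig":
        """Point every input at a generator bundle directory."""
        d = Path(bundle_dir)
        with open(d / BUNDLE_FILES["manifest"]) as fh:
            gcfg = json.load(fh)["config"]
        peak_paths = {
            f: {t: {"fdr1": str(d / peak_file_name(f, t, 1)),
                    "fdr25": str(d / peak_file_name(f, t, 25))}
                for t in (gcfg["tissue_a"], gcfg["tissue_b"])}
            for f in gcfg["factors"]}
        kwargs = dict(
            out_dir=str(out_dir), factors=list(gcfg["factors"]),
            tissue_a=gcfg["tissue_a"], tissue_b=gcfg["tissue_b"],
            peak_paths=peak_paths,
            chrom_sizes=str(d / BUNDLE_FILES["chrom_sizes"]),
            fasta=str(d / BUNDLE_FILES["fasta"]),
            genes=str(d / BUNDLE_FILES["genes"]),
            segmentation=str(d / BUNDLE_FILES["segmentation"]),
            conservation=str(d / BUNDLE_FILES["conservation"]),
            uces=str(d / BUNDLE_FILES["uces"]),
            enhancers=str(d / BUNDLE_FILES["enhancers"]),
            gene_sets=str(d / BUNDLE_FILES["gene_sets"]),
            motif_patterns=dict(gcfg["motif_patterns"]),
            promoter_window=int(gcfg["promoter_window"]),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def validate(self) -> None:
        for factor in self.factors:
            for tissue in (self.tissue_a, self.tissue_b):
                for tier in ("fdr1", "fdr25"):
                    p = self.peak_paths[factor][tissue][tier]
                    if not Path(p).exists():
                        raise ValidationError(f"missing peak file {p}")
        if not Path(self.chrom_sizes).exists():
            raise ValidationError(f"missing chrom sizes {self.chrom_sizes}")


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _optional(path: str | None) -> str | None:
    return path if path and Path(path).exists() else None


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "skipped": [], "provenance": _provenance(config)}

    sizes = tio.read_chrom_sizes(config.chrom_sizes)
    if _optional(config.fasta):
        assembly = tio.read_fasta(config.fasta, chrom_sizes=sizes)
    else:
        assembly = GenomeAssembly(chrom_sizes=sizes)

    # -- stage: classify ----------------------------------------------------
    log.info("stage classify: dual-FDR specificity labels")
    results = {}
    class_sets: dict[str, list] = {}
    counts_rows = []
    for factor in config.factors:
        tiers = {}
        for tissue in (config.tissue_a, config.tissue_b):
            paths = config.peak_paths[factor][tissue]
            tiers[tissue] = DualTierPeakSet(
                factor=factor, tissue=tissue,
                fdr1_peaks=tio.read_bed(paths["fdr1"], "peak", factor=factor,
                                        tissue=tissue, fdr_tier=1),
                fdr25_peaks=tio.read_bed(paths["fdr25"], "peak", factor=factor,
                                         tissue=tissue, fdr_tier=25))
        res = classify(tiers[config.tissue_a], tiers[config.tissue_b])
        results[factor] = res
        for tissue, (shared, specific) in res.counts().items():
            counts_rows.append({"factor": factor, "tissue": tissue,
                                "shared": shared, "specific": specific})
        class_sets[f"{factor}_shared"] = shared_consensus(res)
        class_sets[f"{factor}_specific_{config.tissue_b}"] = res.subset(
            config.tissue_b, Label.SPECIFIC)
        class_sets[f"{factor}_specific_{config.tissue_a}"] = res.subset(
            config.tissue_a, Label.SPECIFIC)
        for tissue in (config.tissue_a, config.tissue_b):
            labelled = [
                ScoredPeak(GenomicInterval(c.peak.chrom, c.peak.start, c.peak.end,
                                           strand=c.peak.interval.strand,
                                           name=c.label.value),
                           factor=factor, tissue=tissue, fdr_tier=1, score=c.peak.score)
                for c in res.calls[tissue]]
            tio.write_bed(labelled, out / f"calls_{factor}_{tissue}.bed")
    counts = pd.DataFrame(counts_rows)
    _write_tsv(counts, out / "classification_counts.tsv")
    report["stages"]["classify"] = counts.to_dict(orient="records")

    # -- stage: overlap matrices --------------------------------------------
    log.info("stage overlap: pairwise co-occurrence matrix")
    nonempty = {k: v for k, v in class_sets.items() if v}
    if len(nonempty) >= 2:
        mat = pairwise_matrix(nonempty, assembly, bin_width=config.bin_width)
        _write_tsv(mat, out / "cooccurrence_matrix.tsv")
        report["stages"]["overlap"] = {"n_sets": len(nonempty)}
    else:
        report["skipped"].append("overlap: fewer than two non-empty peak classes")

    # -- stage: annotation ---------------------------------------------------
    genes = None
    if _optional(config.genes):
        log.info("stage annotate: genomic-region breakdown")
        genes = tio.read_gene_models(config.genes)
        rows = []
        for name, peaks in nonempty.items():
            frac = region_breakdown(peaks, genes, promoter_window=config.promoter_window)
            rows.append({"set": name, **{k.value: v for k, v in frac.items()}})
        breakdown = pd.DataFrame(rows)
        _write_tsv(breakdown, out / "region_breakdown.tsv")
        report["stages"]["annotate"] = breakdown.to_dict(orient="records")
    else:
        report["skipped"].append("annotate: no gene models supplied")

    # -- stage: targets + gene-set enrichment --------------------------------
    if genes is not None:
        log.info("stage targets: regulatory-logic partition")
        logic_rows = []
        enrich_frames = []
        library = tio.read_gmt(config.gene_sets) if _optional(config.gene_sets) else None
        for factor in config.factors:
            calls = [c for tissue in results[factor].calls
                     for c in results[factor].calls[tissue]]
            assignments = assign_targets(calls, genes,
                                         max_distance=config.target_max_distance)
            for a in assignments:
                logic_rows.append({"factor": factor, "gene_id": a.gene_id,
                                   "logic_class": a.logic_class.value,
                                   "n_peaks": len(a.calls)})
            if library is not None:
                universe = [g.gene_id for g in genes]
                specific_only = [a.gene_id for a in assignments
                                 if a.logic_class.value == "SPECIFIC_ONLY"]
                if specific_only:
                    enr = gene_set_enrichment(specific_only, universe, library)
                    enr.insert(0, "factor", factor)
                    enrich_frames.append(enr)
        logic = pd.DataFrame(logic_rows).sort_values(
            ["factor", "gene_id"], kind="stable")
        _write_tsv(logic, out / "gene_logic_classes.tsv")
        report["stages"]["targets"] = {
            f: logic[logic["factor"] == f]["logic_class"].value_counts().to_dict()
            for f in config.factors}
        if enrich_frames:
            _write_tsv(pd.concat(enrich_frames, ignore_index=True),
                       out / "gene_set_enrichment.tsv")
        elif library is None:
            report["skipped"].append("enrich: no gene-set library supplied")
    else:
        report["skipped"].append("targets: no gene models supplied")

    # -- stage: motifs --------------------------------------------------------
    segmentation = tio.read_bed(config.segmentation, "segmentation") \
        if _optional(config.segmentation) else None
    if assembly.sequence is not None and config.motif_patterns:
        log.info("stage motifs: containment fractions and central enrichment")
        frac_rows = []
        contrast_rows = []
        for factor, text in config.motif_patterns.items():
            pattern = IUPACPattern.parse(text, name=f"{factor}_motif")
            for cls in ("shared", f"specific_{config.tissue_b}",
                        f"specific_{config.tissue_a}"):
                peaks = class_sets.get(f"{factor}_{cls}", [])
                if not peaks:
                    continue
                fr = peak_motif_fraction(peaks, assembly, pattern)
                frac_rows.append({"factor": factor, "class": cls, "state": "ALL",
                                  "with_motif": fr.numerator, "n": fr.denominator,
                                  "fraction": fr.fraction})
                if segmentation is not None:
                    by_state: dict[str, list] = {}
                    for p in peaks:
                        iv = getattr(p, "interval", p)
                        by_state.setdefault(
                            segmentation.label_at(iv.chrom, iv.center), []).append(p)
                    state_fr = {}
                    for state, sp in sorted(by_state.items()):
                        fr_s = peak_motif_fraction(sp, assembly, pattern)
                        state_fr[state] = fr_s
                        frac_rows.append({"factor": factor, "class": cls,
                                          "state": state,
                                          "with_motif": fr_s.numerator,
                                          "n": fr_s.denominator,
                                          "fraction": fr_s.fraction})
                    if "BLUE" in state_fr and "YELLOW" in state_fr:
                        a, b = state_fr["BLUE"], state_fr["YELLOW"]
                        p_val = compare_fractions(a.numerator, a.denominator,
                                                  b.numerator, b.denominator)
                        contrast_rows.append({
                            "factor": factor, "class": cls,
                            "blue_fraction": a.fraction,
                            "yellow_fraction": b.fraction, "p_value": p_val})
        _write_tsv(pd.DataFrame(frac_rows), out / "motif_fractions.tsv")
        if contrast_rows:
            contrasts = pd.DataFrame(contrast_rows)
            _write_tsv(contrasts, out / "motif_state_contrasts.tsv")
            report["stages"]["motifs"] = contrasts.to_dict(orient="records")
        # central enrichment of the configured consensus motifs in the
        # specific class of each factor, peaks resized around centres
        library = MotifLibrary(motifs=[IUPACPattern.parse(t, name=f"{f}_motif")
                                       for f, t in config.motif_patterns.items()])
        ce_rows = []
        for factor in config.factors:
            peaks = class_sets.get(f"{factor}_specific_{config.tissue_b}", [])
            seqs = _centered_sequences(peaks, assembly, config.central_window)
            if len(seqs) >= 20:
                for r in central_enrichment(seqs, library,
                                            e_threshold=config.e_value_threshold):
                    ce_rows.append({"peak_set": f"{factor}_specific_{config.tissue_b}",
                                    **r.__dict__})
        if ce_rows:
            _write_tsv(pd.DataFrame(ce_rows), out / "central_enrichment.tsv")
    else:
        report["skipped"].append("motifs: no genome sequence or no patterns supplied")

    # -- stage: conservation / chromatin context ------------------------------
    if _optional(config.conservation):
        log.info("stage context: conservation profiles")
        track = tio.read_bedgraph(config.conservation, assembly)
        prof_frames = []
        for name, peaks in nonempty.items():
            prof = profile_scores(peaks, track, halfwidth=config.profile_halfwidth)
            prof_frames.append(pd.DataFrame({
                "set": name, "offset": prof.positions,
                "mean_score": prof.mean_score, "n": prof.n_contributing}))
        _write_tsv(pd.concat(prof_frames, ignore_index=True),
                   out / "conservation_profiles.tsv")
        report["stages"]["conservation"] = {"sets": sorted(nonempty)}
    else:
        report["skipped"].append("conservation: no track supplied")

    if _optional(config.uces):
        uces = tio.read_bed(config.uces)
        rows = [{"set": name, "uce_fraction": uce_overlap_fraction(peaks, uces)}
                for name, peaks in nonempty.items()]
        _write_tsv(pd.DataFrame(rows), out / "uce_overlap.tsv")
    else:
        report["skipped"].append("uces: no ultraconserved elements supplied")

    if segmentation is not None:
        log.info("stage context: chromatin-state enrichment")
        frames = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, peaks in nonempty.items():
                tbl = state_enrichment_table(
                    state_enrichment(peaks, segmentation, assembly,
                                     bin_width=config.bin_width))
                tbl.insert(0, "set", name)
                frames.append(tbl)
        states = pd.concat(frames, ignore_index=True)
        _write_tsv(states, out / "state_enrichment.tsv")
        report["stages"]["states"] = {
            name: states[states["set"] == name]
            .sort_values("fraction", ascending=False)["state"].iloc[0]
            for name in nonempty}
    else:
        report["skipped"].append("states: no segmentation supplied")

    # -- stage: enhancer summary ----------------------------------------------
    if _optional(config.enhancers):
        log.info("stage enhancers: catalog overlap summary")
        catalog = tio.read_enhancer_catalog(config.enhancers)
        frames = []
        for name, peaks in nonempty.items():
            tbl = summarize_enhancer_overlap(peaks, catalog)
            tbl.insert(0, "set", name)
            frames.append(tbl)
        _write_tsv(pd.concat(frames, ignore_index=True), out / "enhancer_overlap.tsv")
        report["stages"]["enhancers"] = {"n_fragments": len(catalog)}
    else:
        report["skipped"].append("enhancers: no catalog supplied")

    for notice in report["skipped"]:
        log.warning("skipped %s", notice)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _centered_sequences(peaks, assembly, window: int) -> list[str]:
    from .core import GenomicInterval
    seqs = []
    half = window // 2
    for p in peaks:
        iv = getattr(p, "interval", p)
        c = iv.center
        size = assembly.chrom_sizes[iv.chrom]
        if c - half < 0 or c + half > size:
            continue
        seqs.append(assembly.fetch(GenomicInterval(iv.chrom, c - half, c + half)))
    return seqs


def _provenance(config: RunConfig) -> dict:
    # out_dir is excluded: where outputs land must not change their content
    payload = {k: v for k, v in config.__dict__.items() if k != "out_dir"}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return {
        "version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "defaults": {
            "bin_width": config.bin_width,
            "promoter_window": config.promoter_window,
            "target_max_distance": config.target_max_distance,
            "profile_halfwidth": config.profile_halfwidth,
            "e_value_threshold": config.e_value_threshold,
        },
    }
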