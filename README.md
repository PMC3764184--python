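# tisschip

Tissue-context analysis of transcription-factor ChIP peak calls.

When the same factor is profiled in two tissues — say the eye-antenna (EA)
and wing (W) imaginal discs of *Drosophila* — the interesting question is
rarely "where does it bind" but "where does it bind *differently*".
`tisschip` implements a conservative dual-FDR-threshold rule for that
question and a set of statistics for characterising the resulting classes
of binding events, plus a seeded synthetic-data generator that produces
every input the pipeline consumes together with a ground-truth manifest.

## The classification rule

Peaks are called at two stringencies per tissue: a stringent 1% FDR tier
and a permissive 25% FDR tier. A peak called at FDR 1% in one tissue is

* **tissue-specific** (W>EA or EA>W) if it overlaps *no* FDR 25% call in
  the other tissue — not even a marginal one; and
* **tissue-shared** (EA≈W) if it overlaps at least one (≥ 1 bp, half-open
  intervals).

Requiring absence at the permissive tier makes the "specific" label robust
to peaks hovering around the stringent threshold; quantitative differences
in binding strength are deliberately out of scope.

Each class is then characterised by:

* **Interval co-occurrence** — the genome is tiled into fixed-width bins
  (default 1 kb); with N bins, n hit by set A, K hit by set B and k hit by
  both, k is hypergeometric(N, K, n) under independence, giving an
  upper-tail p-value, expected overlap nK/N and an observed/expected ratio.
* **Genomic-region breakdown** — each peak centre gets exactly one label
  with precedence PROMOTER (1 kb strand-aware window upstream of a TSS) >
  EXON > INTRON > INTERGENIC, so fractions sum to 1.
* **Regulatory-logic partition** — target genes (peak overlaps gene body or
  falls within 10 kb of the TSS) are split into shared-only,
  shared-plus-specific and specific-only classes, with hypergeometric
  gene-set enrichment (Benjamini–Hochberg corrected) per class.
* **Motif content** — binary IUPAC consensus scanning on both strands,
  including spaced dimers such as `TGAY[N0-2]TGAY` (0–2 unconstrained bases
  between half-sites); per-class/per-state containment fractions compared
  with Fisher's exact test; and a central-enrichment test (binomial upper
  tail on best matches near peak centres, E-value = p × motif-library
  size, significant at E ≤ 10).
* **Conservation and chromatin context** — mean conservation profiles
  ±500 bp around peak centres, ultraconserved-element overlap (≥ 50 bp
  perfect-identity runs), and enrichment across the five-colour chromatin
  states (YELLOW/RED active, BLUE Polycomb, GREEN/BLACK silent).
* **Enhancer-catalog overlap** — fragments bound by each class, the
  fraction active per tissue, and the unique-CRM count after merging
  partially overlapping fragments.

## Worked example

```python
from tisschip import GeneratorConfig, generate, load_bundle, classify, Label
from tisschip.annotation import region_breakdown, RegionLabel
from tisschip.motifs import IUPACPattern, peak_motif_fraction, compare_fractions

generate(GeneratorConfig(seed=42), "bundle")      # full synthetic input set
b = load_bundle("bundle")
res = classify(b.peak_sets[("Sd", "EA")], b.peak_sets[("Sd", "W")])
print(res.counts())

shared_w = res.subset("W", Label.SHARED)
print(region_breakdown(shared_w, b.genes)[RegionLabel.PROMOTER])

pat = IUPACPattern.parse("GGAATG")
spec = res.subset("W", Label.SPECIFIC)
by_state = {}
for p in spec:
    by_state.setdefault(b.segmentation.label_at(p.chrom, p.interval.center), []).append(p)
blue = peak_motif_fraction(by_state["BLUE"], b.assembly, pat)
yellow = peak_motif_fraction(by_state["YELLOW"], b.assembly, pat)
print(blue.fraction, yellow.fraction,
      compare_fractions(blue.numerator, blue.denominator,
                        yellow.numerator, yellow.denominator))
```

prints

```
{'EA': (1200, 150), 'W': (1200, 2000)}
0.4633333333333333
0.5164473684210527 0.41919191919191917 0.0029349...
```

Read: the wing tier contains 1200 shared and 2000 wing-specific events
versus only 150 eye-antenna-specific ones (the planted wing-rich
asymmetry); 46.3% of shared events sit in promoters; and the GGAATG
motif is present in 51.6% of wing-specific peaks in Polycomb (BLUE)
chromatin versus 41.9% in active (YELLOW) chromatin, a significant
contrast (Fisher two-sided p ≈ 2.9 × 10⁻³).

The same pipeline is available from the shell:

```sh
tisschip simulate --seed 42 --out bundle
tisschip run-all --bundle bundle --out results
```

which writes labelled call BEDs, the co-occurrence matrix, region
breakdowns, gene-logic classes, motif and state-enrichment tables,
conservation profiles and the enhancer summary as TSV files plus a JSON
run report.

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic scenario from
scratch for a given seed, re-verifies the generator's ground-truth
manifest against the emitted files, runs every pipeline stage and writes
the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/tisschip/
  core.py         data model, interval primitives
  io.py           BED/GFF3/BED12/FASTA/bedGraph/wiggle/GMT/TSV readers+writers
  specificity.py  dual-FDR classification
  overlap.py      binned hypergeometric co-occurrence, enhancer summaries
  annotation.py   region breakdown, target genes, gene-set enrichment
  motifs.py       IUPAC/dimer scanning, Fisher contrasts, central enrichment
  context.py      conservation profiles, UCEs, chromatin-state enrichment
  simulate.py     synthetic bundle generator + manifest validation
  pipeline.py     stage orchestration
  cli.py          `tisschip` command
```

See `docs/methods.md` for the statistical model, generator design and
known limitations.
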