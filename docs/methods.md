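# Methods

## Coordinate and overlap conventions

All intervals are 0-based half-open `[start, end)`. BED input is native;
GFF3 (1-based closed) is converted on read. "Overlap" always means at
least one shared base, so abutting intervals never overlap; no
reciprocal-fraction requirement is imposed anywhere. A peak's centre is
`floor((start + end) / 2)`. Chromosome names are matched by exact string
comparison; no "chr" aliasing is attempted.

## Dual-FDR specificity classification

Each tissue contributes a stringent (1% FDR) and a permissive (25% FDR)
peak tier; threshold nesting — every stringent peak overlaps a permissive
peak of the same tissue — is *enforced at load* rather than silently
repaired, because a violation indicates inconsistent peak calling, not a
recoverable condition. A stringent peak is SPECIFIC iff it overlaps none
of the partner tissue's permissive peaks, SHARED otherwise. Shared events
are counted per tissue (each tissue's stringent peaks are labelled
independently); `shared_consensus` merges the shared peaks of both
tissues into one region list for downstream modules that need a single
set. Invariants tested: trichotomy (every stringent peak gets exactly one
label), swap symmetry, and monotonicity (enlarging the partner's
permissive tier never converts SHARED to SPECIFIC).

## Co-occurrence null model

The upstream literature delegates overlap significance to an external
tool whose internal unit is not printed, so this package uses an explicit
and enumerable null: the genome is tiled into fixed-width bins (default
1 kb, configurable), a bin is "hit" when ≥ 1 interval of a set overlaps
it, and the number of doubly hit bins under independence is
hypergeometric. This makes the test exactly reproducible and
oracle-testable (direct pmf summation agrees to < 1e-10 relative error
for universes ≤ 1000 bins). Whether "expected overlap" should account for
interval widths rather than bin counts is not recoverable from the
source; widths enter only through which bins an interval touches.
P-values are floored at the smallest positive double rather than reported
as 0, and −ln(p) is capped accordingly. Empty sets yield p = 1 and a NaN
ratio with a warning instead of an error so that sparse classes degrade
gracefully inside matrices.

## Region breakdown and target assignment

Region labels are decided at the peak centre so that every peak receives
exactly one label and class-level fractions sum to 1 (the pie-chart
contract). Precedence is PROMOTER > EXON > INTRON > INTERGENIC; the
promoter is the strand-aware 1 kb window upstream of the TSS
(`[tss−1000, tss)` on +, `(tss, tss+1000]` on −). A gene is targeted by a
peak iff the peak overlaps the gene body or lies within 10 kb of the TSS
(both configurable). The 10 kb window is a pragmatic default: real
enhancers in this system can act at > 30 kb, so distal regulation is
systematically missed — a known limitation, which is why the window is a
flag rather than a constant. Gene-set enrichment uses the upper-tail
hypergeometric with Benjamini–Hochberg correction across sets; no GO DAG
propagation is performed (sets are consumed flat from GMT).

## Motif statistics

Consensus matching is binary IUPAC class membership on both strands; an
`N` in the sequence is treated as unknown and matches only the pattern
symbol `N`. Spaced dimers `X[Na-b]Y` expand to one concrete pattern per
spacer length; half-site placements never overlap. "Containing the motif"
means ≥ 1 match anywhere within the called peak interval on either
strand. Fraction contrasts use Fisher's exact two-sided test
(minimum-likelihood convention, matching the exact-enumeration oracle).

Central enrichment takes, per motif, the single best match per sequence
(PWM: top log-odds under a uniform 0.25 background; consensus: any
match), with ties broken toward the peak centre and then leftmost. Every
centre-symmetric window over the candidate start positions is tested with
a binomial upper tail whose success probability is window positions /
total positions; the best window's p is Bonferroni-multiplied by the
number of windows tested, so the reported p is calibrated
(approximately uniform under uniform placement — verified by a KS test
over 200 simulated null sets). The E-value is p × library size and the
significance threshold defaults to E ≤ 10.

## Conservation and chromatin context

Profiles average the track value per offset in ±500 bp around peak
centres; gaps in the track are missing data, excluded from that offset's
mean rather than zero-filled. Ultraconserved elements are maximal runs of
≥ 50 perfectly identical bases in a binary identity track (the run finder
exists mainly so synthetic tests need no external UCE download; real UCE
BEDs are consumed directly). Peak→state assignment uses the centre,
giving exclusive fractions that sum to 1 over the five states; because
"overlapping a state" is ambiguous for wide peaks, an any-overlap
counting mode is available behind a flag. Peaks whose centre falls in a
segmentation gap go to an explicit UNASSIGNED bucket with a warning.

## Synthetic-data generator

The generator emulates the statistical regime of two-tissue
tiling-array ChIP for three factors (a coactivator and two DNA-binding
factors) on a 4 × 2.5 Mb genome:

| parameter | default | rationale |
|---|---|---|
| stringent peaks, wing | 3200 (Sd/Hth) | wing-rich asymmetry: ~2000 wing-specific |
| stringent peaks, eye-antenna | 1350 (Sd/Hth) | 150 eye-specific + 1200 shared |
| shared fraction (of wing tier) | 0.375 (Sd/Hth), 0.945 (Yki) | coactivator binding is mostly shared |
| permissive-tier inflation | 0.5 decoys per stringent peak | nesting plus realistic permissive excess |
| peak half-width / permissive pad | 150 bp / 100 bp | tiling-array-scale resolution |
| promoter share | 0.46 shared, 0.08 specific | shared events are promoter-biased |
| state shares | Y .20 R .15 B .15 G .15 K .35 | five-colour genome composition |
| state bias, specific class | BLUE .32, RED .25, … | Polycomb bias of specific events |
| motif rate by state | BLUE .51, YELLOW .37, RED .45, else .40 | state-dependent motif content |
| conservation | 0.9 inside flagged peaks, 0.1 outside | specific peaks flagged at 0.5, shared 0.15 |
| UCE rate | 0.30 specific, 0.05 shared | ultraconservation biased to specific |

Design points that make recovery tests sharp rather than approximate:

* One occupancy bitmap per factor guarantees that within a factor no two
  emitted intervals of any tier overlap except the deliberate
  cross-tissue shared pairs, so shared/specific ground truth is exact.
* Non-promoter peaks reject positions inside any promoter window, so the
  planted promoter share is exact, not merely expected.
* Segment labels fill per-state length quotas in random order, so realized
  genome state shares match the stated shares to within one segment;
  otherwise share drift (a few percent with i.i.d. labels) distorts
  enrichment ratios against the stated world.
* Motif content is controlled per peak by a Bernoulli flag at the
  configured rate: flagged peaks get one realization of the pattern
  planted near the centre (never overwriting another factor's planted
  site); unflagged peaks are scrubbed — background matches are mutated
  away, re-scanning until clean — so the observed containment fraction
  equals the planted rate up to binomial noise, independent of the
  background match probability of the pattern.
* Background sequence is i.i.d. uniform A/C/G/T. This is the simplest
  null consistent with binary consensus matching; it does not reproduce
  the dinucleotide composition, repeat content or GC heterogeneity of a
  real genome, so motif-rate absolute values on real data will differ
  even when the planted contrasts are recovered.
* One RNG stream per output type, all derived from the master seed, so
  adding a new output never perturbs existing ones; the same seed yields
  byte-identical bundles.

What a green recovery test establishes: the pipeline correctly recovers
planted class labels, promoter shares, state biases, motif-rate
contrasts and conservation elevation from files on disk. What it does
not establish: robustness to peak-boundary noise between tiers and
tissues (shared peaks are emitted with identical coordinates in both
tissues), to unbalanced chromosome sizes, or to the correlated structure
of real chromatin domains.

## Pipeline

Stages recompute rather than cache (inputs are desk-scale), run in
dependency order, and skip with an explicit notice when an optional
input is absent. All thresholds with published defaults (FDR tiers 1/25,
1 kb promoter, ±500 bp profile, 50 bp UCE, E ≤ 10) are configuration
fields, not constants. Reruns on identical inputs and configuration are
byte-identical; for that reason the provenance block carries a config
hash, package version and seed but no wall-clock timestamps, and the
output directory path is excluded from the config hash.

## Numerical choices

* Hypergeometric/binomial tails come from scipy (`sf`), Fisher's exact
  from `scipy.stats.fisher_exact`, BH from statsmodels.
* Central-enrichment ties (equal PWM score or equidistant matches) break
  toward the centre, then leftmost; the convention is arbitrary but
  fixed and documented.
* Degenerate inputs: empty peak class → co-occurrence p = 1 with
  warning; empty gene list → enrichment rows with hits 0; peaks too
  close to a chromosome edge for the central-enrichment window are
  dropped from that analysis.
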