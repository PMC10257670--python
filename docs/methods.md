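# Methods

This note documents the models and procedures histokit implements, the
parameters that matter, the numerical choices made where a convention was
genuinely open, and what the synthetic-data generators do and do not emulate.

## Coordinate and strand conventions

All coordinates are 0-based, half-open (BED convention) internally; any
1-based display is formatting only. A stranded read is reduced to its 5'-most
aligned base: the start of a Watson (`+`) read, `end - 1` of a Crick (`-`)
read. For paired-end SAM input the fragment's strand is taken from the first
mate only, and secondary, supplementary and unmapped records are skipped; BED6
is the canonical read format and SAM support is a convenience layer.
Overlapping intervals within one annotation track are merged before any
bp-length arithmetic so no base is counted twice.

## eSPAN strand bias (`espan_bias`)

For each replication origin, Watson and Crick read 5' ends are counted into
fixed-width bins across a window of ±`half_window` (default 250 kb) and the
per-bin statistic

    bias = (W − C) / (W + C)

is formed. Bins with `W + C = 0` are *undefined* (NaN), not zero: absence of
reads is not evidence of strand balance. Defined values lie in [−1, 1] and
negate exactly under a W/C relabeling of the reads.

**Control normalization.** The BrdU-IP-ssSeq control is reduced to its own
bias profile on the same origins and geometry and subtracted bin-wise.
Subtraction removes additive technical strand bias while keeping the zero
point interpretable ("no preference"); division-based alternatives entangle
depth with bias. After subtraction values lie in [−2, 2]; a bin is defined
only where both operands are.

**Smoothing.** A centered moving average over ±`flank_bins` bins (default
1000, i.e. 100 kb at 100-bp bins), ignoring undefined bins inside the window
and truncating at the array edges rather than padding — padding would invent
data at the profile boundary.

**Aggregation and fold.** Profiles are averaged across origins per bin,
ignoring NaNs; the meta profile records how many origins contributed to each
bin. The leading-strand score folds the meta profile as

    score = (mean bias over left-flank bins − mean over right-flank bins) / 2.

Under the package's sign convention — leading-strand nascent reads map to
Watson left of the origin and to Crick right of it — a positive score is a
leading-strand preference, and on simulated data the score estimates
`2·p_lead − 1` where `p_lead` is the leading-strand transfer probability.

One interaction deserves care: when the profile has been smoothed, the moving
average straddles the origin for bins closer than `flank_bins` to the center,
mixing bins whose expected bias has opposite sign. Including those bins
attenuates the fold by roughly `flank_bins/(2·K)` relative (about 20% at the
defaults). The fold therefore excludes bins within `flank_bins` of the origin
from both flank means; this keeps the score an unbiased estimate of
`2·p_lead − 1` while leaving the smoothed profile itself untouched for
plotting. If the smoothing flank is as large as the half-window, no usable
bins remain and the fold raises an error rather than guessing.

Origins whose window would cross a chromosome boundary are dropped with a
warning, never clipped, so count matrices stay rectangular.

## Differential peaks and annotation enrichment (`peak_reprogramming`)

**Classifier.** The dispersion-modeling machinery of dedicated
differential-binding packages is deliberately not reimplemented; downstream
statistics depend only on the up/stable/down partition. The stand-in is:
`log2FC = log2((mean mutant FPKM + ε)/(mean WT FPKM + ε))` with pseudocount
ε = 0.1 FPKM (configurable), and a two-sided two-sample t-test on
`log2(FPKM + ε)` across replicates when both conditions have ≥ 2 replicates
(else p = 1). Zero-variance replicate groups (possible in noiseless
simulations) get p = 0 when the means differ and p = 1 otherwise. Thresholds:
up iff `log2FC > 1` and `p < 0.01`; down is the mirror; else stable.

**Annotation.** Each peak takes the highest-priority annotation type whose
track contains the peak midpoint (priority: promoter > 5'UTR > 3'UTR > exon >
intron > TTS > CpG island > LINE > SINE > LTR > simple repeat > satellite;
types not listed are appended at lowest priority). No hit → intergenic. A
midpoint rule with a single label is deterministic and matches common
annotation practice.

**Enrichment ratio.** For a differential set (merged length `L_d`) and its
stable counterpart (`L_s`) against an annotation track (`L_anno`) on a genome
of length `L_g`:

    obs  = bp overlap(peak set, track)
    exp  = (L_anno / L_g) · L_set
    ratio = log2((obs_d / exp_d) / (obs_s / exp_s))

The `L_anno/L_g` factor cancels, so the ratio equals
`log2((obs_d/L_d)/(obs_s/L_s))`; the implementation computes the full form
and the test suite asserts equality with the cancelled form to 1e-12, which
also settles the ambiguity in which of the two lengths is "peak" vs "target"
in the expectation — both readings give the same ratio. The ratio is flagged
undefined when either observed overlap is zero; no pseudocount is injected.

**Compartments.** A peak is assigned the compartment label (A or B) with the
larger bp overlap; zero overlap or an exact tie leaves it unassigned. The
majority rule is a package decision — peaks spanning compartment boundaries
have no canonical assignment.

**Enhancers.** H3K4me1 peaks are classified by a fixed cascade: overlap with
any H3K4me3 peak → not an enhancer; midpoint within 2.5 kb of a TSS →
excluded; overlap with H3K27ac → active; else overlap with H3K27me3 →
repressed; else poised. The TSS exclusion is inclusive at exactly 2.5 kb.

## Binned signal and change-ratio correlation (`signal_quant`)

The genome is tiled into 10-kb bins (final partial bin kept) and per-bin FPKM
is computed as `count / ((length/1e3) · (total_mapped/1e6))`. Change ratios
are `(mutant + ε)/(WT + ε)` with ε = 0.1 FPKM; bins where both signals are
exactly zero are undefined and excluded downstream. Pairwise Pearson
correlations between marks are computed on **log2** ratios — raw ratios
weight a doubling and a halving asymmetrically — over bins defined in both
marks (pairwise deletion); pairs with fewer than 3 shared bins are skipped
with a warning. A pair is flagged "displayed" when its two-sided p < 0.01.

Meta profiles bin read densities (± 10 kb, 100-bp bins by default) around
anchor points, scaled to FPKM per bin; anchors whose window crosses a
chromosome edge are dropped, matching the bias module. Gene-body profiles use
100 length-relative bins oriented TSS→TES by gene strand, because genes of
unequal length cannot share an absolute-scale average; the per-gene
absolute-scale FPKM is also returned.

## Clone calling (`clone_lineage`)

Triples (cell barcode, UMI, lineage barcode, read count) are filtered to
≥ 10 reads; lineage barcodes are collapsed by greedy abundance-ranked
clustering (descending total read support, lexicographic tie-break; each
barcode joins the highest-ranked representative within hamming distance ≤ 3,
else founds its own), which is deterministic and idempotent. Each cell is
assigned to the lineage with maximal distinct-UMI support if that support is
≥ 3; exact ties leave the cell unassigned — a conservative doublet rule. The
UMI threshold applies per (cell, lineage) pair. Lineages with ≥ 2 assigned
cells are clones; clones are grouped by size (2–10, 11–20, > 20) and clones
with more than 20 cells are flagged dominant. Size-group summaries report the
percentage of clone-member cells per group and sum to 100 per sample.

## Study statistics (`study_stats`)

The 2×2 incidence comparison is a Pearson chi-square without continuity
correction, computed from the closed form
`N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))` with a chi-square(1) upper-tail p.
On the 6/8-vs-2/8 table this gives X² = 4.0 and p = 0.0455. Zero margins
raise (test undefined). Tumor volume is the standard caliper ellipsoid
approximation `0.52 · length · width²` (mm³); measurements are swapped with a
warning if width exceeds length.

## Synthetic data (`synthetic_data`)

All generators take a frozen config plus a seed and are byte-deterministic.

* **eSPAN**: origins evenly spaced on one synthetic chromosome so no window
  crosses an edge; each origin emits a fixed number of reads, side chosen
  uniformly, offset uniform over the half-window (no fragment-size decay —
  the uniform offset is the simplest model consistent with window-limited
  counting). A read is leading-type with probability `p_lead` and mapped to
  W/C by the convention above. A technical `control_bias` b is planted
  additively in *both* read sets (eSPAN uses `p_lead + b/2`, control
  `0.5 + b/2`), so control subtraction cancels it by construction. Defaults
  (200 origins × 500 reads, `p_lead` 0.875) give the folded score a sampling
  sd of ≈ 0.015.
* **Peaks**: a regular promoter lattice on a 10-Mb toy chromosome; each peak
  is placed entirely inside the track with its category's planted
  probability (defaults 0.5 differential / 0.25 stable → expected enrichment
  ratio `log2 2 = 1`) or entirely in a gap. Planted |log2FC| is drawn from
  [1.5, 3]; replicate FPKM = mean × lognormal(σ = 0.1), 2 replicates.
* **Binned marks**: per-bin log2 ratios from a multivariate normal with the
  planted correlation matrix (default 2 marks, ρ = 0.8, 2,000 bins); WT is a
  shared lognormal baseline per bin and mutant = WT · 2^z, so the planted
  correlation survives the ratio transform exactly.
* **Barcodes**: clone sizes geometric (mean 8, truncated at 1 — small enough
  to populate the 2–10 group, heavy-tailed enough to produce > 20 dominant
  clones at 30 clones); planted barcodes are drawn with pairwise hamming ≥ 8
  so collapse clusters cannot bridge clones. Each emitted barcode copy
  carries **at most one** substitution (probability 0.1): single-base PCR/
  sequencing errors dominate at these read depths, and the cap keeps every
  variant within the collapse radius of its planted barcode.
* **Genome annotation**: fixed-length features on a double-pitch lattice
  (disjoint by construction) covering configured fractions; A/B compartments
  tile each chromosome alternately with no gaps.

What the generators do **not** emulate: fragment-length and GC biases,
replication-timing structure, indels and quality scores, barcode doublets,
and spatially autocorrelated signal. Passing recovery tests therefore
demonstrates correctness of the statistics under their stated sampling
models, not robustness to every artifact of real libraries.

## Problem sizes and tolerances

Recovery tests run at the generator defaults above (the conditions the
statistics were designed around): 100 seeded replicates for the bias score at
200 × 500 reads (pass band |error| < 0.05 in ≥ 95%), 1,000 replicates for the
null calibration of the correlation display gate (rate 1% ± 1 point), 50
seeds for exact clone recovery, and means over 50–100 seeds for the
enrichment-ratio checks (a single 500-peak draw has sampling sd ≈ 0.13 on the
ratio, so point checks are run on seed-averaged means against the ±0.15
band). Exact identities (cancelled-form equality, bias antisymmetry, greedy
collapse vs brute force) are asserted to 1e-12 or exactly.
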