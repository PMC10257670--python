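# histokit

Analysis toolkit for studying **replication-coupled histone inheritance** and
its downstream epigenomic consequences. When a replication fork passes,
parental histones — carrying modifications such as H3K27me3 and H3K36me3 —
are recycled to the two daughter strands; mutations that disturb this
partition (e.g. the MCM2 histone-binding-domain 2A mutant) reshape the
chromatin landscape and can drive clonal evolution in cancer cells. histokit
implements the bespoke computations such a study needs, each verifiable on
synthetic data with planted ground truth:

* **eSPAN strand bias** (`histokit.espan_bias`): around each replication
  origin, Watson/Crick read counts per 100-bp bin give
  `Bias = (W − C)/(W + C)`; profiles are BrdU-control-subtracted, smoothed
  (± 1000 bins), averaged over origins, and folded into a signed
  leading-strand score that estimates `2·p_lead − 1`, the excess probability
  of parental-histone transfer to the leading strand.
* **Peak reprogramming** (`histokit.peak_reprogramming`): up/stable/down peak
  classification (|log2FC| > 1, p < 0.01), Homer-like midpoint annotation,
  and the relative enrichment ratio
  `log2((obs_d/exp_d)/(obs_s/exp_s))` with `exp = (L_anno/L_g)·L_set`;
  A/B-compartment proportions per category; enhancer classification from
  H3K4me1/H3K4me3/H3K27ac/H3K27me3 co-occupancy with a 2.5-kb TSS exclusion.
* **Binned signal correlation** (`histokit.signal_quant`): 10-kb genome bins,
  FPKM, mutant/WT change ratios, pairwise Pearson correlation of log2 ratios
  with a p < 0.01 display gate, and ± 10 kb / 100-bp meta profiles.
* **Clone calling** (`histokit.clone_lineage`): LARRY-style lineage-barcode
  clone calling — triples with ≥ 10 reads, hamming-3 greedy collapse, ≥ 3
  distinct UMIs per cell; clone size groups 2–10 / 11–20 / > 20 with > 20
  flagged dominant.
* **Study statistics** (`histokit.study_stats`): Pearson 2×2 chi-square
  (no continuity correction) and the caliper tumor volume
  `0.52 · length · width²`.
* **Synthetic data** (`histokit.synthetic_data`): seeded generators with
  ground truth for every stage, so the whole pipeline is testable without
  any external download.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Simulate an eSPAN experiment in which parental histones move to the leading
strand with probability `p_lead = 0.875` (200 origins, 500 reads each, plus
an unbiased BrdU control), then run the full bias pipeline:

```python
from histokit.synthetic_data import simulate_espan_experiment, EspanSimConfig
from histokit.espan_bias import espan_bias_pipeline

sim = simulate_espan_experiment(EspanSimConfig(p_lead=0.875), seed=1)
meta, summary = espan_bias_pipeline(
    sim.espan_reads, sim.control_reads, sim.origins,
    chrom_sizes=sim.chrom_sizes,
)
print(f"leading_bias_score {summary.leading_bias_score:.4f}")
print(summary.n_origins_used, summary.n_bins_defined)
```

prints

```
leading_bias_score 0.7345
200 3000
```

The score recovers `2·0.875 − 1 = 0.75` to within sampling error (sd ≈ 0.015
at this depth): a strong leading-strand preference, as seen for H3K36me3
eSPAN in MCM2-2A mutant cells. The same pipeline is available from the shell:

```bash
histokit simulate espan --seed 1 --out sim/
histokit bias --origins sim/origins.bed --espan sim/espan_reads.bed \
    --control sim/control_reads.bed --chrom-sizes sim/genome.chrom.sizes \
    --out sim/result
```

The in-paper metastasis statistic:

```bash
$ histokit stats chi2 --table 6,2,2,6
statistic	4.0000
pvalue	0.046
```

(6/8 vs 2/8 incidence; X² = 4.0, p = 0.0455.)

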