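# pausepoint

Quantitative analysis of RNA polymerase II **3′ pausing** and
**transcriptional interference (TI)** between closely spaced tandem genes,
from ChIP-seq coverage tracks and RNA-seq differential-expression tables.

In plants, Pol II accumulates just downstream of the transcript end site
(TES) of expressed genes.  When this 3′ pause is lost, the polymerase of a
highly expressed gene can read through into the promoter of a close,
same-strand downstream neighbor and repress it.  `pausepoint` implements
the analyses needed to quantify this phenomenon genome-wide:

- **3′ pausing index** per gene: the ratio of read densities
  `PI = d(TES, TES + w] / d[TSS, TES)` with densities in FP10M/bp
  (fragments per 10 million aligned fragments), compared between
  conditions by paired Student's *t* on `log2 PI` within expression
  groups, with Benjamini–Hochberg (BH) adjustment.
- **Metagene profiles**: winsorized average coverage anchored on TSS/TES
  or scaled over 100 gene-body bins, with Gaussian 95% confidence bands
  (`mean ± 1.96·sd/√n`).
- **TES-shift estimation**: the displacement of the 3′ pausing maximum
  between conditions, `Δ = argmax(profile_b) − argmax(profile_a)` within a
  TES ± 1 kb window, at population and per-gene level, with one-sided
  Wilcoxon signed-rank group tests against the all-genes baseline.
- **Genomic context statistics**: neighbor orientation (tandem /
  divergent / convergent), intergenic-distance distributions
  (Kolmogorov–Smirnov vs all genes), upstream-neighbor expression
  (Mann–Whitney U), and gene-loop enrichment (Fisher exact), all
  BH-adjusted per family.
- **TI selection procedures** on tandem gene pairs (< 600 bp apart) from a
  light-shift experiment: an arm whose upstream gene is light-induced
  (fold-change > 2, padj < 0.05 in all light-vs-dark contrasts) vs a
  not-DE arm (fold-change < 1.5, padj > 0.2), removal of pairs with
  pre-existing TI (raw p < 0.05 in the dark), and paired Wilcoxon tests of
  the downstream gene's log2(mutant/wt) ratio between dark and light.
- **Peak annotation** by strict precedence (promoter → immediate
  downstream → 5′UTR → 3′UTR → exon → intron → intergenic, with 300 bp
  windows) and empirical enrichment against random genomic positions.
- **Blacklist construction** from control ChIP tracks (95th percentile of
  a negative binomial fitted to random bin samples, majority rule across
  controls) and **nucleosome-free region** calling (> 500 bp of joint
  MNase + H3 signal below the genome-wide first quartile).
- A fully ground-truthed **synthetic study generator** that emulates the
  structure of such a study — gene layouts with controlled pair
  orientations and intergenic distances, Poisson-noised Pol II coverage
  with condition-dependent TES bumps, negative-binomial RNA-seq counts
  with planted differential expression and light-dependent TI, control
  tracks with artifact hot regions — so every analysis stage can be
  validated against a recoverable planted truth.

## Worked example

```python
from pausepoint import synthetic, pausing, shift

study = synthetic.simulate_study(seed=7)          # 600 genes, wt + mutant
wt = study.tracks[("wt", "polii")]
mut = study.tracks[("mutant", "polii")]
genes = study.genes[1:-1]

est = shift.population_shift(wt, mut, genes)
print(f"population TES shift: {est.shift:+d} bp "
      f"(wt max at {est.offset_a:+d}, mutant at {est.offset_b:+d}; "
      f"n={est.n_genes} genes)")

wt_pi = pausing.pausing_table(wt, genes, condition="wt")
mut_pi = pausing.pausing_table(mut, genes, condition="mutant")
row = pausing.compare_pausing(wt_pi, mut_pi).iloc[0]
print(f"mean log2 pausing index: wt {row.mean_log2_pi_a:.2f} vs "
      f"mutant {row.mean_log2_pi_b:.2f} "
      f"(paired t = {row.t:.1f}, BH-adjusted p = {row.padj:.2e})")
```

prints

```
population TES shift: +97 bp (wt max at +51, mutant at +148; n=598 genes)
mean log2 pausing index: wt 0.16 vs mutant -0.73 (paired t = -64.7, BH-adjusted p = 1.02e-253)
```

The simulated mutant halves the TES bump amplitude and moves it 96 bp
downstream; the pipeline recovers the displacement (+97 bp here) and the
drop in mean log2 pausing index (~0.9 log2 units, i.e. roughly the halved
bump amplitude) with an overwhelmingly significant paired test.

The same operations are exposed as a CLI for file-based pipelines:

```sh
pausepoint simulate --seed 7 --out sim/
pausepoint pausing sim/wt_polii.bedGraph sim/annotation.gff3 \
    --chrom-sizes sim/chrom.sizes --tes-window 200 --out pi.tsv
pausepoint shift sim/wt_polii.bedGraph sim/mutant_polii.bedGraph \
    sim/annotation.gff3 --chrom-sizes sim/chrom.sizes --out shift.tsv
```

Inputs are plain-text interchange formats: GFF3 or BED6/BED12
annotations, bedGraph or fragment-BED coverage, narrowPeak-style peaks,
TSV differential-expression tables, and two-column chrom.sizes files.
Internally all coordinates are 0-based half-open.

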