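# Methods

This note documents the models, conventions and numerical choices behind
`pausepoint`, in the order data flows through the pipeline.

## Coordinates and annotations

All internal coordinates are 0-based half-open (BED convention); GFF3's
1-based closed intervals are converted on read and write, so both
round-trip losslessly.  A gene is represented by its genomic span: the
TSS is the first transcribed base (`start` on +, `end-1` on −) and the
TES the last.  Multi-isoform structure is out of scope — where a real
annotation offers several transcripts per locus, the caller should
collapse to a gene-level span first.  Sub-features (UTRs, exons) are
optional; introns are derived as the gene span minus exons when not
explicit, because GFF3 dialects differ on whether introns are annotated.

**Neighbor contexts.**  The neighbor on each genomic side of a focal gene
is the gene with the nearest border, skipping pairs where one gene fully
contains the other (nested genes are not informative neighbors).  Sides
are relabelled upstream/downstream according to the focal strand.  The
intergenic distance is the half-open border gap (`down.start − up.end`);
an upstream gene ending at 1000 (exclusive) with a downstream TSS at
1244 is 244 bp away.  Overlapping pairs get distance 0 plus an `overlap`
flag and are excluded from distance distributions.  Pair classes: tandem
(same strand), divergent (head-to-head on the upstream side), convergent
(tail-to-tail on the downstream side).

**Peak annotation.**  Summits are classified by strict precedence:
promoter (< 300 bp upstream of a TSS, strand-aware) → immediate
downstream (< 300 bp past a TES) → 5′UTR → 3′UTR → exon → intron →
intergenic (≥ 300 bp from any gene span, strand-agnostic).  The windows
are strict (distance in the open interval (0, 300)); a summit exactly
300 bp from a gene is intergenic.  Genes without sub-features count their
whole body as exonic.  Ties among genes within the winning category break
by summit-to-anchor distance, then lexicographic gene id, so annotation
is reproducible.  Enrichment against the genomic background is empirical:
`n_samples` replicate sets of `len(peaks)` uniform positions over the
non-blacklisted genome are classified by the same rules, and the
two-sided p-value is `2·min(tail count + 1)/(n_samples + 1)`.

**Gene sets.**  Expression groups are quantile-based with ties kept in
one group (the group of the lowest-ranked occurrence), which reproduces
the unequal group sizes quantile grouping yields on tied data.  Not-DE
controls require p > 0.45 and |log2FC| < 0.25 in *every* listed contrast
plus basemean strictly inside (3, 1e5).  Expression-matched controls are
drawn by stratified sampling over 20 quantile bins of the reference set's
expression (20 bins balances resolution against per-bin counts at the
~1500-control scale); unfillable bin quotas are redistributed to bins
with remaining candidates, with a warning if the pool runs out.

## Coverage

Tracks are dense per-bp vectors per chromosome.  Fragment coverage is
the count of fragments overlapping each base; FP10M multiplies every
value by `1e7 / total_fragments`, making the normalization linear in
library size.  bedGraph is the required text interchange (bit-exact,
dependency-light); fragment BED input accepts an optional length filter
(e.g. 70–250 bp for nucleosome-associated data, an upstream convention
honored at read time).  Overlapping bedGraph intervals are an error, not
a merge.

**Blacklist.**  The genome is cut into 1 kb bins (size chosen to resolve
typical artifact regions while keeping per-bin counts Poisson-stable).
Per control track, a negative binomial is fitted by method of moments to
each of 100 random bin samples of size 30,000 (capped at the number of
bins with a warning on small genomes; Poisson fallback when variance ≤
mean), and the track's threshold is the *median* of the fitted 95th
percentiles.  Bins exceeding their track's threshold in more than half of
the controls are flagged and adjacent flagged bins merged.  The random
bin samples are drawn once and shared across tracks, which makes the
result invariant to control ordering under a fixed seed.  Manual
genome-browser refinement of such lists is inherently irreproducible and
is not part of the contract.

**Nucleosome-free regions.**  Genome-wide first quartiles are computed
per track over *all* bases (zeros included); NFRs are maximal runs
strictly longer than 500 bp where MNase and H3 signal are both below
their Q1, minus any excluded regions.  An all-zero track pins Q1 at 0 and
yields an empty result with a warning.

## Metagene profiles

Windows are extracted strand-aware (minus-strand windows reversed), so
offsets always increase in the direction of transcription.  Windows
truncated at chromosome edges contribute only to the offsets they cover
(per-offset `n`), rather than dropping the gene.  Across the selected
window set, the most extreme upper 0.01% of values are replaced by the
99.99th-percentile value before averaging — one-sided capping only, since
artifact signal is additive.  The winsorization pool is the full window
set of the current plot (per gene set, per track), so the cap adapts to
the selection.  Confidence bands are `mean ± z·sd/√n` with
`z = 1.959964`; the normal approximation tracks bootstrap bands closely
at metagene sample sizes, so no bootstrap is implemented.  Gene-body
profiles map each body to 100 equal-fraction bins (per-gene bin means);
genes shorter than 100 bp sample shared bases.  Flanks are unbinned for
profiles and 20 bp-binned for heatmap grids.

`profile_argmax` returns the offset of the maximum mean within a search
window; exact ties break toward the anchor (smallest |offset|), then
toward the lower offset, and a flat window returns the anchor-proximal
bound with a warning.

## Pausing index

For each expressed gene longer than 1 kb, the body region is
`[TSS + trim0, TES − trim1)` and the TES region the `tes_window_bp` bases
immediately downstream of the TES, both along transcription.  Defaults:
`tes_window_bp = 200` (the 3′ bump sits within ~200 bp of the TES; every
recovery property here holds for any fixed window) and `body_trim =
(0, 0)` (whole body; trims exposed for sensitivity analysis).  Density is
sum/length, so the index is invariant to any global rescaling of the
track.  Genes with zero body density are flagged undefined and excluded
rather than imputed — no pseudocount enters `log2 PI`.  A TES window that
truncates at a chromosome edge or reaches into the next gene body is
computed but flagged (intrusion into the neighbor is exactly the
phenomenon of interest).  Condition comparisons are paired Student's *t*
tests on `log2 PI` per expression group and antibody, BH-adjusted over
all tests of the run; groups with fewer than 3 valid pairs are NA.

## TES shift

The population shift is `argmax(profile_b) − argmax(profile_a)` on
TES-anchored winsorized average profiles over the same gene set, within a
±1 kb window.  Per-gene shifts use the same argmax rule on raw
(unwinsorized, unsmoothed) per-gene windows; genes whose window maximum
does not exceed `min_signal` (default 0) in both tracks are dropped.
Argmax was chosen over cross-correlation because it matches the
population definition and needs no shape assumption; an optional boxcar
smoother exists for very noisy inputs but is off by default.  Group
shifts are tested one-sided (greater) against the mean shift of all
expressed genes by Wilcoxon signed-rank, BH across groups × antibodies.

A per-profile caveat: the argmax of a noisy average profile carries
bp-scale jitter (the top of a bump is locally flat), so single-replicate
shift estimates are accurate to a few bp, not exactly; accuracy improves
with gene count and bump amplitude.  The acceptance suite therefore
checks the mean recovered shift across 50 independent simulations against
the planted value (±2 bp) and per-gene medians within ±10 bp.

## TI selection and statistics

From tandem pairs with border gap < 600 bp:

- *Induction arm* (light experiment): upstream gene up-regulated by light
  with fold-change > 2 (strict, i.e. log2FC > 1) and padj < 0.05 in all
  four light-vs-dark contrasts (2 h and 4 h, both genotypes); *not-DE
  arm*: fold-change < 1.5 and padj > 0.2 in all four.  Pairs whose
  downstream gene already shows TI in the dark (raw p < 0.05 with
  negative mutant-vs-wt log2FC — raw p, not padj, because this is an
  exclusion filter where sensitivity matters more than FDR) are removed
  from both arms.
- *Relief arm*: downstream gene with dark TI evidence (raw p < 0.05,
  negative log2FC) and an upstream gene light-downregulated (fold-change
  > 1.5 downward, padj < 0.05) in both genotypes at 2 h or at 4 h, or
  not-DE (fold-change < 1.5, padj > 0.1 in all four contrasts).

Every inequality is strict in the stated direction; boundary fixtures in
the test suite pin each one (fold-change exactly 2 is excluded, dark p
exactly 0.05 carries no TI evidence, etc.).  Arm ratios are compared
dark-vs-light by paired Wilcoxon signed-rank, two-sided by default (the
direction of relief is a finding, not an assumption) with a one-sided
flag.  The distance analysis of light-induced genes bins the distance
from the focal TSS to the nearest border of the upstream gene (< 600,
600–1200, > 1200 bp) and compares same- vs opposite-strand groups per
condition by Mann–Whitney U; BH adjustment is per analysis family
(one family per figure-level question), and any side with fewer than 5
genes is NA.

## Statistical kernels

All tests used by the pipeline are implemented in-repo so that the exact
code paths are validated by enumeration oracles; SciPy supplies only
distribution functions (normal/t CDFs, NB/Poisson quantiles).

- *Wilcoxon signed-rank*: zeros dropped with a warning; for n ≤ 25 the
  null distribution of W⁺ is built by convolution over doubled midranks
  (exact even with ties); above that, normal approximation with tie
  correction and continuity correction.
- *Mann–Whitney U*: midranks; exact enumeration of rank assignments when
  min(n,m) ≤ 8, n+m ≤ 24 and there are no ties (full enumeration is
  intractable when the larger sample is unbounded); otherwise normal
  approximation with tie and continuity corrections.
- *Two-sample KS*: exact D via ECDFs, asymptotic p with the Stephens
  small-sample correction (conservative, never anti-conservative under
  the null at the sizes used here).
- *Fisher exact*: hypergeometric sums via log-gamma; two-sided p is the
  sum of table probabilities not exceeding the observed one (with a 1e−7
  relative slack against floating-point ties); degenerate margins give
  p = 1 with a warning.
- *Paired t*: identical pairs give t = 0, p = 1; a constant non-zero
  difference gives p = 0.
- *BH*: step-up with monotone enforcement, capped at 1; NaNs pass through
  without counting toward the family size.

## Synthetic data generator

The generator is first-class, tested code.  One 600-gene chromosome
(~2 Mb) is laid out head-to-tail: gene lengths log-normal (median 1.8 kb,
σ = 0.45, floor 400 bp — comparable to a compact plant genome), strands
from a Markov chain with P(same as previous) = 0.5, border gaps
log-normal with median 859 bp (σ = 0.9, floor 40 bp).  A protected-like
subset (15% of genes) is chosen so that 74% of it has a same-strand
upstream neighbor; those pairs' gaps are redrawn from a short law
(median 244 bp, σ = 0.5) and the upstream neighbors get +1.32 log2 units
of expression (≈ 2.5-fold).  These constants deliberately mirror the
genomic-context signature the pipeline is designed to detect, so that
demo output is interpretable; the realized (seed-specific) fractions and
medians are recorded as ground truth and are what the analyses are tested
against.

Coverage: expected signal = flat background (0.2/bp) + an
expression-proportional body plateau (linear FPKM × 1.0/bp; a rising ramp
for S2P-like tracks, a TSS bump for S5P-like tracks) + a Gaussian 3′ bump
centered 50 bp downstream of the TES (σ = 25 bp, amplitude 3.5× the
plateau — a sharp, few-fold peak as seen in 3′-pausing data).  In the
mutant the bump amplitude is halved and its center moves 96 bp
downstream for affected genes.  Per-bp values are Poisson-sampled.
Bump σ and amplitude control the argmax jitter discussed above.

RNA-seq: negative-binomial counts (dispersion 0.05, three replicates per
group) for wt/mutant × dark/light 2 h/light 4 h plus three single-mutant
dark groups.  Planted effects: protected −1.5 / repressed +1.5 log2 in
the mutant under all conditions; 50% of genes light-induced (+2.5 log2 at
both time points, both genotypes); genes with a light-induced same-strand
upstream neighbor closer than 600 bp lose 1.2 log2 units in the mutant
under light only — the planted light-dependent TI.  Contrast tables carry
log2FC of replicate means and p-values from a vectorized NB Wald test
whose standard error uses the generative dispersion
(`var(ln μ̂) ≈ (1/μ + α)/n`), emulating a DESeq2-style fit whose
dispersion estimate is accurate; BH is applied per contrast.

Control ChIP tracks have per-kb gamma rate heterogeneity (shape 5, mean
2/bp), giving negative-binomially distributed bin counts, with 10 planted
2 kb hot regions at 20× rate shared by all controls.  Nucleosome tracks
are noiseless plateaus (10/bp) with planted 700 bp valleys (0.5/bp) so
NFR boundaries are exactly recoverable; a Poisson-noised variant exists
for robustness tests.  Gene loops are Bernoulli with rate 0.10, raised to
0.30 for upstream-tandem neighbors of protected genes.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mappability and GC structure, isoform and
alternative-TSS complexity, replicate-level ChIP variability beyond
Poisson counting noise, dispersion trends across expression, correlated
neighbor expression, and genome-scale gene counts (the default 600-gene
chromosome is sized so the full acceptance suite runs in about a minute;
statistics that need scale, such as the 9 expression groups of ~2,500
genes each, are exercised structurally rather than at published size).

## Known limitations

- Shift estimation is argmax-based by design; profiles with two
  comparable TES maxima can flip between them under noise.
- The NFR rule is sensitive to the Q1 of the genome-wide signal
  distribution; on sparse tracks Q1 = 0 makes the rule vacuous (warned).
- The empirical peak-enrichment p-value is bounded below by
  `2/(n_samples+1)`; strongly enriched categories saturate there.
- TI selection consumes differential-expression tables as given; it does
  not refit models or correct for count depth beyond the thresholds the
  procedure specifies.
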