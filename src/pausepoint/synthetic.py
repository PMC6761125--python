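"""Synthetic genomes, coverage, DE tables and loops with ground truth.

The generator emulates the data structure of a plant Pol II ChIP-seq /
RNA-seq study of 3' pausing and tandem-gene transcriptional interference:

* a compact one-chromosome annotation laid head-to-tail with controlled
  pair orientations and log-normal intergenic distances (background
  median 859 bp, 50% tandem adjacency);
* a "protected-like" gene subset that preferentially sits a short
  distance (median 244 bp) downstream of a highly expressed same-strand
  neighbor (74% tandem-upstream rate);
* strand-aware Pol II coverage with an expression-proportional body
  plateau and a Gaussian 3' pausing bump just downstream of the TES whose
  amplitude and position change in the "mutant" condition (default: half
  amplitude, 96 bp downstream shift), with per-bp Poisson noise;
* negative-binomial RNA-seq counts for wt/mutant under dark and two light
  time points, with planted differential expression and a light-dependent
  TI effect restricted to close same-strand pairs with a light-induced
  upstream gene;
* control ChIP tracks with planted artifact "hot" regions, and
  nucleosome-occupancy (MNase/H3-like) tracks with planted valleys.

Every planted quantity is recorded in a GroundTruth object so each
analysis operation has a recoverable truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import stats
from .annotation import GeneModel, ExpressionTable, write_gff3
from .coverage import CoverageTrack


@dataclass
class SimulationConfig:
    # genome layout
    n_genes: int = 600
    chrom: str = "chr1"
    chrom_margin: int = 5000
    gene_len_median: float = 1800.0
    gene_len_sigma: float = 0.45        # log-normal sigma (natural log)
    gene_len_floor: int = 400
    fraction_tandem: float = 0.5        # P(same strand as previous gene)
    intergenic_median: float = 859.0    # background border-gap median (bp)
    intergenic_sigma: float = 0.9
    intergenic_floor: int = 40
    # protected-like structure
    protected_fraction: float = 0.15
    protected_tandem_fraction: float = 0.74
    protected_intergenic_median: float = 244.0
    protected_intergenic_sigma: float = 0.5
    protected_upstream_expr_boost: float = 1.32   # log2 units
    repressed_fraction: float = 0.08
    # expression
    expr_log2_mean: float = 3.0
    expr_log2_sd: float = 1.5
    # ChIP coverage model
    coverage_scale: float = 1.0         # body plateau = scale * linear expr
    background_rate: float = 0.2
    pausing_center: int = 50            # bump center, bp downstream of TES
    pausing_sd: float = 25.0
    pausing_amplitude: float = 3.5      # bump height / body plateau
    tss_center: int = 0
    tss_sd: float = 60.0
    tss_amplitude: float = 2.0          # S5P-like TSS bump
    mutant_amplitude_ratio: float = 0.5
    mutant_shift_bp: int = 96
    affected_gene_fraction: float = 1.0
    # RNA-seq counts
    n_replicates: int = 3
    count_depth: float = 5.0            # mean counts per linear-expr unit/kb
    nb_dispersion: float = 0.05
    de_protected_lfc: float = -1.5      # mutant vs wt, all conditions
    de_repressed_lfc: float = 1.5
    # photomorphogenesis / TI
    light_induced_fraction: float = 0.5
    light_lfc: float = 2.5
    ti_effect_lfc: float = -1.2         # mutant/wt of TI-hit genes in light
    ti_max_distance: int = 600
    # loops
    loop_base_rate: float = 0.10
    loop_protected_upstream_rate: float = 0.30
    # control tracks
    n_controls: int = 4
    control_rate: float = 2.0
    control_gamma_shape: float = 5.0
    n_hot_regions: int = 10
    hot_len: int = 2000
    hot_multiplier: float = 20.0
    # nucleosome tracks
    nuc_baseline: float = 10.0
    nuc_valley_rate: float = 0.5
    n_valleys: int = 5
    valley_len: int = 700


@dataclass
class GroundTruth:
    genes: pd.DataFrame = None           # per-gene planted attributes
    chrom_len: int = 0
    protected: list = field(default_factory=list)
    repressed: list = field(default_factory=list)
    null_genes: list = field(default_factory=list)
    light_induced: list = field(default_factory=list)
    ti_hit: list = field(default_factory=list)
    protected_tandem_fraction: float = float("nan")
    background_tandem_fraction: float = float("nan")
    protected_median_distance: float = float("nan")
    background_median_distance: float = float("nan")
    loops: set = field(default_factory=set)
    loop_rates: dict = field(default_factory=dict)
    hot_regions: list = field(default_factory=list)
    valleys: list = field(default_factory=list)


def _child(rng_or_seed, index: int) -> np.random.Generator:
    """Deterministic child generator #index from a seed or Generator."""
    if isinstance(rng_or_seed, np.random.Generator):
        base = rng_or_seed.integers(0, 2**31 - 1)
    else:
        base = int(rng_or_seed) if rng_or_seed is not None else 0
    return np.random.default_rng(np.random.SeedSequence([base, index]))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def gen_annotation(cfg: SimulationConfig, seed=0):
    """Synthetic gene layout with planted context classes and expression."""
    rng = _child(seed, 1)
    n = cfg.n_genes
    lengths = np.maximum(
        cfg.gene_len_floor,
        np.rint(rng.lognormal(math.log(cfg.gene_len_median),
                              cfg.gene_len_sigma, n))).astype(int)
    # strands: Markov chain, P(same as previous) = fraction_tandem
    strands = np.empty(n, dtype="<U1")
    strands[0] = "+" if rng.random() < 0.5 else "-"
    same_prev = rng.random(n) < cfg.fraction_tandem
    for i in range(1, n):
        if same_prev[i]:
            strands[i] = strands[i - 1]
        else:
            strands[i] = "-" if strands[i - 1] == "+" else "+"
    gaps = np.maximum(
        cfg.intergenic_floor,
        np.rint(rng.lognormal(math.log(cfg.intergenic_median),
                              cfg.intergenic_sigma, n))).astype(int)

    # upstream adjacency: for + genes the upstream neighbor is i-1 (gap i),
    # for - genes it is i+1 (gap i+1)
    up_idx = np.where(strands == "+", np.arange(n) - 1, np.arange(n) + 1)
    valid_up = (up_idx >= 0) & (up_idx < n)
    tandem_up = np.zeros(n, dtype=bool)
    tandem_up[valid_up] = strands[np.clip(up_idx, 0, n - 1)][valid_up] == \
        strands[valid_up]

    # protected set: planted tandem-upstream rate by stratified choice
    n_prot = int(round(cfg.protected_fraction * n))
    want_tandem = int(round(cfg.protected_tandem_fraction * n_prot))
    pool_t = np.nonzero(tandem_up & valid_up)[0]
    pool_nt = np.nonzero(~tandem_up & valid_up)[0]
    take_t = min(want_tandem, len(pool_t))
    take_nt = min(n_prot - take_t, len(pool_nt))
    protected = np.concatenate([
        rng.choice(pool_t, size=take_t, replace=False),
        rng.choice(pool_nt, size=take_nt, replace=False)])
    protected = np.sort(protected)
    is_prot = np.zeros(n, dtype=bool)
    is_prot[protected] = True

    # shrink the upstream gap of protected tandem genes to the short law
    for i in protected:
        if not tandem_up[i]:
            continue
        gap_idx = i if strands[i] == "+" else i + 1
        if 0 < gap_idx < n:
            gaps[gap_idx] = max(
                cfg.intergenic_floor,
                int(round(rng.lognormal(
                    math.log(cfg.protected_intergenic_median),
                    cfg.protected_intergenic_sigma))))

    # repressed set from the remainder
    rest = np.nonzero(~is_prot)[0]
    n_rep = int(round(cfg.repressed_fraction * n))
    repressed = np.sort(rng.choice(rest, size=n_rep, replace=False))
    is_rep = np.zeros(n, dtype=bool)
    is_rep[repressed] = True

    # coordinates
    starts = np.empty(n, dtype=int)
    pos = cfg.chrom_margin
    for i in range(n):
        if i > 0:
            pos += gaps[i]
        starts[i] = pos
        pos += lengths[i]
    chrom_len = pos + cfg.chrom_margin

    # expression (log2 FPKM-like); boost upstream neighbors of protected
    expr = rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd, n)
    for i in protected:
        if tandem_up[i] and valid_up[i]:
            expr[up_idx[i]] += cfg.protected_upstream_expr_boost

    width = len(str(n))
    gene_ids = [f"SYNG{str(i + 1).zfill(width)}" for i in range(n)]
    genes = []
    feat_rng = _child(seed, 2)
    for i in range(n):
        s, e = int(starts[i]), int(starts[i] + lengths[i])
        feats = _gene_features(s, e, strands[i], feat_rng)
        genes.append(GeneModel(gene_ids[i], cfg.chrom, s, e, strands[i],
                               feats))

    up_gap = np.full(n, np.nan)
    for i in range(n):
        if valid_up[i]:
            up_gap[i] = gaps[i] if strands[i] == "+" else gaps[i + 1]
    truth_genes = pd.DataFrame({
        "gene_id": gene_ids, "strand": strands, "start": starts,
        "length": lengths, "expr_log2": expr,
        "tandem_upstream": tandem_up,
        "upstream_gene": [gene_ids[j] if ok else None
                          for j, ok in zip(np.clip(up_idx, 0, n - 1),
                                           valid_up)],
        "upstream_distance": up_gap,
        "de_class": np.where(is_prot, "protected",
                             np.where(is_rep, "repressed", "null")),
        "affected": rng.random(n) < cfg.affected_gene_fraction,
    }).set_index("gene_id")

    prot_mask = truth_genes["de_class"] == "protected"
    tand = truth_genes["tandem_upstream"]
    has_up = truth_genes["upstream_gene"].notna()

    def _frac(num, den):
        return float(num / den) if den else float("nan")

    def _med(values):
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        return float(np.median(values)) if len(values) else float("nan")

    truth = GroundTruth(
        genes=truth_genes, chrom_len=int(chrom_len),
        protected=[gene_ids[i] for i in protected],
        repressed=[gene_ids[i] for i in repressed],
        null_genes=[g for g in gene_ids
                    if truth_genes.loc[g, "de_class"] == "null"],
        protected_tandem_fraction=_frac(
            (prot_mask & tand).sum(), (prot_mask & has_up).sum()),
        background_tandem_fraction=_frac(tand[has_up].sum(), has_up.sum()),
        protected_median_distance=_med(
            truth_genes.loc[prot_mask & tand, "upstream_distance"]),
        background_median_distance=_med(
            truth_genes.loc[tand, "upstream_distance"]),
    )
    return genes, truth


def _gene_features(start, end, strand, rng):
    """Simple exon/UTR structure: UTRs at the ends, 1-2 exons between."""
    length = end - start
    utr = max(30, int(0.08 * length))
    if strand == "+":
        five = ("five_prime_UTR", start, start + utr)
        three = ("three_prime_UTR", end - utr, end)
    else:
        five = ("five_prime_UTR", end - utr, end)
        three = ("three_prime_UTR", start, start + utr)
    mid_s, mid_e = start + utr, end - utr
    feats = [five, three]
    if mid_e - mid_s > 600 and rng.random() < 0.7:
        intron_len = min(200, (mid_e - mid_s) // 4)
        cut = (mid_s + mid_e) // 2
        feats += [("exon", start, cut - intron_len // 2),
                  ("exon", cut + intron_len - intron_len // 2, end)]
    else:
        feats.append(("exon", start, end))
    return tuple(sorted(feats, key=lambda f: (f[1], f[2])))


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------

def _add_gaussian(arr, center, sd, amplitude, lo=None, hi=None):
    half = int(4 * sd)
    s = max(0 if lo is None else lo, int(center) - half)
    e = min(len(arr) if hi is None else hi, int(center) + half + 1)
    if e <= s:
        return
    x = np.arange(s, e) - center
    arr[s:e] += amplitude * np.exp(-0.5 * (x / sd) ** 2)


def expected_coverage(cfg: SimulationConfig, genes, truth: GroundTruth,
                      condition: str = "wt",
                      antibody_profile: str = "polii") -> np.ndarray:
    """Noise-free expected per-bp signal for one condition/antibody."""
    lam = np.full(truth.chrom_len, cfg.background_rate)
    affected = set(truth.genes.index[truth.genes["affected"]])
    if antibody_profile == "control":
        for s, e in truth.hot_regions:
            lam[s:e] += cfg.control_rate * (cfg.hot_multiplier - 1)
        lam += cfg.control_rate
        return lam
    for g in genes:
        expr_lin = 2.0 ** truth.genes.loc[g.gene_id, "expr_log2"]
        plateau = cfg.coverage_scale * expr_lin
        body = np.full(g.length, plateau)
        if antibody_profile == "s2p":
            ramp = np.linspace(0.3, 1.0, g.length)
            body *= ramp if g.strand == "+" else ramp[::-1]
        lam[g.start:g.end] += body
        amp = cfg.pausing_amplitude * plateau
        center = cfg.pausing_center
        if condition == "mutant" and g.gene_id in affected:
            amp *= cfg.mutant_amplitude_ratio
            center += cfg.mutant_shift_bp
        if g.strand == "+":
            bump_pos = g.tes + center
        else:
            bump_pos = g.tes - center
        _add_gaussian(lam, bump_pos, cfg.pausing_sd, amp)
        if antibody_profile == "s5p":
            tss_pos = g.tss + cfg.tss_center if g.strand == "+" \
                else g.tss - cfg.tss_center
            _add_gaussian(lam, tss_pos, cfg.tss_sd,
                          cfg.tss_amplitude * plateau)
    return lam


def gen_coverage(cfg: SimulationConfig, genes, truth: GroundTruth,
                 condition: str = "wt", antibody_profile: str = "polii",
                 seed=0, noise: bool = True) -> CoverageTrack:
    """Poisson-sampled coverage track for one condition and antibody."""
    lam = expected_coverage(cfg, genes, truth, condition, antibody_profile)
    idx = {"wt": 10, "mutant": 11}.get(condition, 12)
    aidx = {"polii": 0, "s2p": 1, "s5p": 2, "control": 3,
            "mnase_like": 4}.get(antibody_profile, 5)
    rng = _child(seed, 100 + 10 * idx + aidx)
    values = rng.poisson(lam).astype(float) if noise else lam
    return CoverageTrack({cfg.chrom: values}, "raw", "unstranded",
                         int(values.sum()))


def gen_control_tracks(cfg: SimulationConfig, truth: GroundTruth, seed=0,
                       bin_heterogeneity_bp: int = 1000):
    """Control ChIP tracks with shared planted hot regions.

    Per-track per-kb gamma rate heterogeneity gives negative-binomial
    binned counts; the hot regions (recorded in truth) are shared by all
    controls.
    """
    rng = _child(seed, 7)
    if not truth.hot_regions:
        n_bins = truth.chrom_len // bin_heterogeneity_bp
        chosen = np.sort(rng.choice(n_bins - 2, size=cfg.n_hot_regions,
                                    replace=False) + 1)
        truth.hot_regions = [
            (int(b * bin_heterogeneity_bp),
             int(b * bin_heterogeneity_bp + cfg.hot_len))
            for b in chosen]
    tracks = []
    for t in range(cfg.n_controls):
        trng = _child(seed, 70 + t)
        n_bins = (truth.chrom_len + bin_heterogeneity_bp - 1) \
            // bin_heterogeneity_bp
        shape = cfg.control_gamma_shape
        rates = trng.gamma(shape, cfg.control_rate / shape, n_bins)
        lam = np.repeat(rates, bin_heterogeneity_bp)[:truth.chrom_len]
        for s, e in truth.hot_regions:
            lam[s:e] *= cfg.hot_multiplier
        values = trng.poisson(lam).astype(float)
        tracks.append(CoverageTrack({cfg.chrom: values}, "raw",
                                    "unstranded", int(values.sum())))
    return tracks


def gen_nucleosome_tracks(cfg: SimulationConfig, truth: GroundTruth, seed=0,
                          noise: bool = False):
    """MNase-like and H3-like occupancy tracks with planted NFR valleys.

    Noiseless by default: the tracks emulate smoothed occupancy, so the
    planted valley boundaries are exactly recoverable.
    """
    rng = _child(seed, 8)
    if not truth.valleys:
        pos = np.sort(rng.choice(
            truth.chrom_len - cfg.valley_len - 2000, size=cfg.n_valleys,
            replace=False) + 1000)
        # enforce separation
        keep = [int(pos[0])]
        for p in pos[1:]:
            if p - keep[-1] > cfg.valley_len + 2000:
                keep.append(int(p))
        truth.valleys = [(p, p + cfg.valley_len) for p in keep]
    tracks = []
    for t in range(2):
        lam = np.full(truth.chrom_len, cfg.nuc_baseline)
        for s, e in truth.valleys:
            lam[s:e] = cfg.nuc_valley_rate
        if noise:
            trng = _child(seed, 80 + t)
            values = trng.poisson(lam).astype(float)
        else:
            values = lam
        tracks.append(CoverageTrack({cfg.chrom: values}, "raw",
                                    "unstranded", int(values.sum())))
    return tracks


# ---------------------------------------------------------------------------
# RNA-seq counts and DE tables
# ---------------------------------------------------------------------------

_GROUPS = [("wt", "dark"), ("wt", "light2"), ("wt", "light4"),
           ("mut", "dark"), ("mut", "light2"), ("mut", "light4"),
           ("bdr1", "dark"), ("bdr2", "dark"), ("bdr3", "dark")]

CONTRASTS = {
    "mut_vs_wt_dark": (("mut", "dark"), ("wt", "dark")),
    "mut_vs_wt_light2": (("mut", "light2"), ("wt", "light2")),
    "mut_vs_wt_light4": (("mut", "light4"), ("wt", "light4")),
    "light2_vs_dark_wt": (("wt", "light2"), ("wt", "dark")),
    "light4_vs_dark_wt": (("wt", "light4"), ("wt", "dark")),
    "light2_vs_dark_mut": (("mut", "light2"), ("mut", "dark")),
    "light4_vs_dark_mut": (("mut", "light4"), ("mut", "dark")),
    "bdr1_vs_wt_dark": (("bdr1", "dark"), ("wt", "dark")),
    "bdr2_vs_wt_dark": (("bdr2", "dark"), ("wt", "dark")),
    "bdr3_vs_wt_dark": (("bdr3", "dark"), ("wt", "dark")),
}


def _nb_wald_p(a: np.ndarray, b: np.ndarray, dispersion: float) -> np.ndarray:
    """Vectorized NB Wald test on replicate count matrices (genes x reps).

    Emulates the output of a DESeq2-style fit whose dispersion estimate is
    accurate: the standard error of the log ratio of group means uses the
    generative dispersion, var(ln mu_hat) ~ (1/mu + alpha) / n.
    """
    from scipy import special
    na, nb = a.shape[1], b.shape[1]
    ma = a.mean(axis=1) + 0.5
    mb = b.mean(axis=1) + 0.5
    se = np.sqrt((1.0 / ma + dispersion) / na
                 + (1.0 / mb + dispersion) / nb)
    z = np.log(ma / mb) / se
    return 2.0 * special.ndtr(-np.abs(z))


def gen_de_tables(cfg: SimulationConfig, genes, truth: GroundTruth,
                  seed=0) -> ExpressionTable:
    """Negative-binomial counts and per-contrast DE tables.

    Planted effects: protected/repressed genes shift mutant-vs-wt in all
    conditions; light-induced genes shift light-vs-dark in both genotypes;
    TI-hit genes (same-strand upstream neighbor closer than
    ``ti_max_distance`` that is itself light-induced) lose expression in
    the mutant under light only.  P-values are NB Wald tests on the
    replicate counts (known-dispersion standard errors), BH-adjusted per
    contrast.
    """
    rng = _child(seed, 3)
    tg = truth.genes
    n = len(tg)
    gene_ids = list(tg.index)
    lengths = tg["length"].values

    light = rng.random(n) < cfg.light_induced_fraction
    truth.light_induced = [g for g, m in zip(gene_ids, light) if m]
    light_set = set(truth.light_induced)
    ti_hit = np.zeros(n, dtype=bool)
    for i, g in enumerate(gene_ids):
        up = tg["upstream_gene"].iloc[i]
        if (tg["tandem_upstream"].iloc[i] and up in light_set
                and tg["upstream_distance"].iloc[i] < cfg.ti_max_distance):
            ti_hit[i] = True
    truth.ti_hit = [g for g, m in zip(gene_ids, ti_hit) if m]
    tg["light_induced"] = light
    tg["ti_hit"] = ti_hit

    mut_lfc = np.where(tg["de_class"] == "protected", cfg.de_protected_lfc,
                       np.where(tg["de_class"] == "repressed",
                                cfg.de_repressed_lfc, 0.0))
    base = cfg.count_depth * (2.0 ** tg["expr_log2"].values) \
        * lengths / 1000.0
    base = np.maximum(base, 0.5)

    means = {}
    for genotype, condition in _GROUPS:
        mu = base.copy()
        if genotype == "mut":
            mu = mu * 2.0 ** mut_lfc
        if condition in ("light2", "light4"):
            mu = mu * np.where(light, 2.0 ** cfg.light_lfc, 1.0)
            if genotype == "mut":
                mu = mu * np.where(ti_hit, 2.0 ** cfg.ti_effect_lfc, 1.0)
        means[(genotype, condition)] = mu

    counts = {}
    disp = cfg.nb_dispersion
    for gi, key in enumerate(_GROUPS):
        grng = _child(seed, 30 + gi)
        mu = means[key]
        r = 1.0 / disp
        p = r / (r + mu)
        counts[key] = np.column_stack([
            grng.negative_binomial(r, p) for _ in range(cfg.n_replicates)
        ]).astype(float)

    contrasts = {}
    for name, (ka, kb) in CONTRASTS.items():
        a, b = counts[ka], counts[kb]
        lfc = np.log2((a.mean(axis=1) + 0.5) / (b.mean(axis=1) + 0.5))
        p = _nb_wald_p(a, b, disp)
        contrasts[name] = pd.DataFrame({
            "log2fc": lfc, "pvalue": p, "padj": stats.bh_adjust(p),
        }, index=gene_ids)

    wt_dark = counts[("wt", "dark")]
    rpkm = wt_dark / lengths[:, None] * 1000.0 \
        / wt_dark.sum(axis=0, keepdims=True) * 1e6
    all_counts = np.column_stack(list(counts.values()))
    genes_df = pd.DataFrame({
        "mean_expression": np.log2(rpkm.mean(axis=1) + 1e-6),
        "basemean": all_counts.mean(axis=1),
    }, index=gene_ids)
    return ExpressionTable(genes_df, contrasts)


def mutant_ratio_frame(expr: ExpressionTable) -> pd.DataFrame:
    """Per-gene log2(mutant/wt) under dark, light2 and light4."""
    return pd.DataFrame({
        "dark": expr.contrast("mut_vs_wt_dark")["log2fc"],
        "light2": expr.contrast("mut_vs_wt_light2")["log2fc"],
        "light4": expr.contrast("mut_vs_wt_light4")["log2fc"],
    })


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------

def gen_loops(cfg: SimulationConfig, truth: GroundTruth, seed=0) -> set:
    """Bernoulli gene-loop membership with context-dependent rates.

    Upstream tandem neighbors of protected genes loop at
    ``loop_protected_upstream_rate``; all other genes at
    ``loop_base_rate``.
    """
    rng = _child(seed, 4)
    tg = truth.genes
    prot_up = set(
        tg.loc[(tg["de_class"] == "protected") & tg["tandem_upstream"],
               "upstream_gene"].dropna())
    loops = set()
    rates = {}
    for g in tg.index:
        rate = cfg.loop_protected_upstream_rate if g in prot_up \
            else cfg.loop_base_rate
        rates[g] = rate
        if rng.random() < rate:
            loops.add(g)
    truth.loops = loops
    truth.loop_rates = {"protected_upstream": cfg.loop_protected_upstream_rate,
                        "base": cfg.loop_base_rate,
                        "n_protected_upstream": len(prot_up)}
    return loops


# ---------------------------------------------------------------------------
# Whole-study bundle and file export
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    cfg: SimulationConfig
    genes: list
    truth: GroundTruth
    tracks: dict            # (condition, antibody) -> CoverageTrack
    expr: ExpressionTable
    loops: set

    @property
    def chrom_sizes(self):
        return {self.cfg.chrom: self.truth.chrom_len}


def simulate_study(cfg: SimulationConfig | None = None, seed=0,
                   antibodies=("polii",), conditions=("wt", "mutant"),
                   with_de: bool = True,
                   with_loops: bool = True) -> SimulatedStudy:
    """One full simulated study: annotation, coverage, DE tables, loops."""
    cfg = cfg or SimulationConfig()
    genes, truth = gen_annotation(cfg, seed)
    tracks = {}
    for cond in conditions:
        for ab in antibodies:
            tracks[(cond, ab)] = gen_coverage(cfg, genes, truth, cond, ab,
                                              seed)
    expr = gen_de_tables(cfg, genes, truth, seed) if with_de else None
    loops = gen_loops(cfg, truth, seed) if with_loops else set()
    return SimulatedStudy(cfg, genes, truth, tracks, expr, loops)


def write_study(study: SimulatedStudy, outdir):
    """Export a simulated study as GFF3 / bedGraph / TSV / JSON files."""
    import os
    from .coverage import write_bedgraph

    os.makedirs(outdir, exist_ok=True)
    write_gff3(study.genes, os.path.join(outdir, "annotation.gff3"))
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for c, s in study.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    for (cond, ab), track in study.tracks.items():
        write_bedgraph(track, os.path.join(outdir, f"{cond}_{ab}.bedGraph"))
    if study.expr is not None:
        study.expr.genes.to_csv(os.path.join(outdir, "expression.tsv"),
                                sep="\t")
        for name, tab in study.expr.contrasts.items():
            tab.to_csv(os.path.join(outdir, f"de_{name}.tsv"), sep="\t")
    with open(os.path.join(outdir, "loops.tsv"), "w") as fh:
        fh.write("gene_id\n")
        for g in sorted(study.loops):
            fh.write(g + "\n")
    truth = {
        "chrom_len": study.truth.chrom_len,
        "protected": study.truth.protected,
        "repressed": study.truth.repressed,
        "light_induced": study.truth.light_induced,
        "ti_hit": study.truth.ti_hit,
        "protected_tandem_fraction": study.truth.protected_tandem_fraction,
        "background_tandem_fraction": study.truth.background_tandem_fraction,
        "protected_median_distance": study.truth.protected_median_distance,
        "background_median_distance": study.truth.background_median_distance,
        "hot_regions": study.truth.hot_regions,
        "valleys": study.truth.valleys,
        "loops": sorted(study.truth.loops),
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
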