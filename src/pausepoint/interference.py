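"""Genomic-context and transcriptional-interference (TI) statistics.

Covers: orientation fractions of regulated gene sets, intergenic-distance
KS tests, upstream-neighbor expression comparisons, gene-loop Fisher
enrichment, and the light-shift (photomorphogenesis) TI selection and
testing procedures on tandem gene pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .annotation import ExpressionTable

LOG2_15 = math.log2(1.5)


@dataclass
class RegulatedGeneSets:
    """Genes protected (down in mutant), repressed (up), and not-DE."""

    protected: set
    repressed: set
    not_de: set

    def __post_init__(self):
        self.protected = set(self.protected)
        self.repressed = set(self.repressed)
        self.not_de = set(self.not_de)
        if (self.protected & self.repressed or
                self.protected & self.not_de or
                self.repressed & self.not_de):
            raise ValueError("regulated gene sets must be disjoint")

    def items(self):
        return [("protected", self.protected),
                ("repressed", self.repressed),
                ("not_de", self.not_de)]


def regulated_sets_from_de(expr: ExpressionTable, contrast: str,
                           padj_max: float = 0.05,
                           not_de_genes=None) -> RegulatedGeneSets:
    """Build protected/repressed sets from a mutant-vs-wt contrast."""
    tab = expr.contrast(contrast)
    sig = tab["padj"] < padj_max
    protected = set(tab.index[sig & (tab["log2fc"] < 0)])
    repressed = set(tab.index[sig & (tab["log2fc"] > 0)])
    not_de = set(not_de_genes or []) - protected - repressed
    return RegulatedGeneSets(protected, repressed, not_de)


# ---------------------------------------------------------------------------
# Context statistics (orientation, distances, upstream expression, loops)
# ---------------------------------------------------------------------------

def orientation_fractions(sets: RegulatedGeneSets, contexts: pd.DataFrame,
                          distance_bins=(400, 800, 1600, float("inf"))
                          ) -> pd.DataFrame:
    """Fraction of each gene set with a neighbor of each orientation
    within each distance cutoff, per side, with the all-genes background.
    """
    named = sets.items() + [("all", set(contexts["gene_id"]))]
    rows = []
    for name, genes in named:
        for side in ("upstream", "downstream"):
            sub_all = contexts[(contexts["side"] == side)]
            sub_all = sub_all[sub_all["gene_id"].isin(genes)]
            denom = len(sub_all)
            for orientation in ("same_strand", "opposite_strand"):
                for cutoff in distance_bins:
                    if denom == 0:
                        frac = np.nan
                    else:
                        hit = sub_all[(sub_all["orientation"] == orientation)
                                      & (sub_all["distance"] <= cutoff)]
                        frac = len(hit) / denom
                    rows.append({"set": name, "side": side,
                                 "orientation": orientation,
                                 "max_distance": cutoff, "n": denom,
                                 "fraction": frac})
    return pd.DataFrame(rows)


def _tandem_distances(contexts: pd.DataFrame, genes=None) -> np.ndarray:
    sub = contexts[(contexts["side"] == "upstream")
                   & (contexts["pair_class"] == "tandem")
                   & (~contexts["overlap"].astype(bool))]
    if genes is not None:
        sub = sub[sub["gene_id"].isin(genes)]
    return sub["distance"].dropna().values.astype(float)


def distance_distribution_tests(sets: RegulatedGeneSets,
                                contexts: pd.DataFrame,
                                min_pairs: int = 5) -> pd.DataFrame:
    """KS test of each set's upstream-tandem intergenic distances vs all
    genes, with BH correction across sets."""
    background = _tandem_distances(contexts)
    rows = []
    for name, genes in sets.items():
        d = _tandem_distances(contexts, genes)
        row = {"set": name, "n_pairs": len(d),
               "median_bp": float(np.median(d)) if len(d) else np.nan,
               "background_median_bp": float(np.median(background))}
        if len(d) < min_pairs:
            row.update(ks_D=np.nan, p=np.nan)
        else:
            res = stats.ks_two_sample(d, background)
            row.update(ks_D=res.statistic, p=res.p)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["padj"] = stats.bh_adjust(out["p"].values)
    return out


def upstream_expression_test(sets: RegulatedGeneSets, contexts: pd.DataFrame,
                             expr: ExpressionTable,
                             alternative: str = "two_sided") -> pd.DataFrame:
    """Mann-Whitney U comparisons of upstream-tandem-neighbor expression.

    Compares the wild-type expression (log2 RPKM-like) of upstream tandem
    neighbors of protected genes against those of not-DE controls and of
    repressed genes; neighbors must have a non-null read count
    (basemean > 0).
    """
    def neighbor_expr(genes):
        sub = contexts[(contexts["side"] == "upstream")
                       & (contexts["pair_class"] == "tandem")
                       & contexts["gene_id"].isin(genes)]
        nbs = [n for n in sub["neighbor_id"] if n in expr.genes.index]
        tab = expr.genes.loc[nbs]
        tab = tab[tab["basemean"] > 0]
        return tab["mean_expression"].values

    prot = neighbor_expr(sets.protected)
    rows = []
    for other_name, other_genes in (("not_de", sets.not_de),
                                    ("repressed", sets.repressed)):
        other = neighbor_expr(other_genes)
        row = {"comparison": f"protected_vs_{other_name}",
               "n_protected": len(prot), "n_other": len(other),
               "median_protected": float(np.median(prot)) if len(prot) else np.nan,
               "median_other": float(np.median(other)) if len(other) else np.nan}
        if len(prot) == 0 or len(other) == 0:
            row.update(U=np.nan, p=np.nan)
        else:
            res = stats.mann_whitney_u(prot, other, alternative)
            row.update(U=res.statistic, p=res.p)
        rows.append(row)
    return pd.DataFrame(rows)


def loop_enrichment(sets: RegulatedGeneSets, contexts: pd.DataFrame,
                    loops, universe=None,
                    alternative: str = "greater") -> pd.DataFrame:
    """Fisher-exact gene-loop enrichment per genomic context.

    Contexts are each regulated set itself plus its upstream/downstream
    neighbors on the same/opposite strand; each is tested for loop
    membership against the rest of the universe, with BH across contexts.
    """
    loops = set(loops)
    if universe is None:
        universe = set(contexts["gene_id"])
    universe = set(universe)
    ctx_members = {}
    for name, genes in sets.items():
        ctx_members[f"{name}"] = genes & universe
        for side in ("upstream", "downstream"):
            for orientation, label in (("same_strand", "same"),
                                       ("opposite_strand", "opposite")):
                sub = contexts[(contexts["side"] == side)
                               & (contexts["orientation"] == orientation)
                               & contexts["gene_id"].isin(genes)]
                members = set(sub["neighbor_id"].dropna()) & universe
                ctx_members[f"{name}_{side}_{label}"] = members
    rows = []
    for label, members in ctx_members.items():
        n_total = len(members)
        n_loop = len(members & loops)
        rest = universe - members
        table = [[n_loop, n_total - n_loop],
                 [len(rest & loops), len(rest) - len(rest & loops)]]
        res = stats.fisher_exact_2x2(table, alternative)
        rows.append({"context": label, "n_with_loops": n_loop,
                     "n_total": n_total,
                     "pct_with_loops": 100.0 * n_loop / n_total
                     if n_total else np.nan,
                     "odds_ratio": res.statistic, "p": res.p})
    out = pd.DataFrame(rows)
    out["padj"] = stats.bh_adjust(out["p"].values)
    return out


# ---------------------------------------------------------------------------
# Photomorphogenesis TI procedures
# ---------------------------------------------------------------------------

@dataclass
class TIDesign:
    """Maps the required photomorphogenesis contrasts to table names.

    ``light_vs_dark``: (genotype, time_h) -> contrast name for genotype in
    {"wt", "mut"}, time in {2, 4}; ``mutant_vs_wt``: condition in
    {"dark", "light2", "light4"} -> contrast name.
    """

    light_vs_dark: dict = field(default_factory=dict)
    mutant_vs_wt: dict = field(default_factory=dict)

    @classmethod
    def default(cls):
        return cls(
            light_vs_dark={("wt", 2): "light2_vs_dark_wt",
                           ("wt", 4): "light4_vs_dark_wt",
                           ("mut", 2): "light2_vs_dark_mut",
                           ("mut", 4): "light4_vs_dark_mut"},
            mutant_vs_wt={"dark": "mut_vs_wt_dark",
                          "light2": "mut_vs_wt_light2",
                          "light4": "mut_vs_wt_light4"},
        )

    def validate(self, expr: ExpressionTable):
        for name in list(self.light_vs_dark.values()) + \
                list(self.mutant_vs_wt.values()):
            expr.contrast(name)


def tandem_pairs(contexts: pd.DataFrame, d_max: int = 600) -> pd.DataFrame:
    """Same-strand (up_gene, down_gene) pairs with border gap < d_max."""
    sub = contexts[(contexts["side"] == "upstream")
                   & (contexts["pair_class"] == "tandem")
                   & (~contexts["overlap"].astype(bool))
                   & (contexts["distance"] < d_max)]
    return pd.DataFrame({
        "up_gene": sub["neighbor_id"].values,
        "down_gene": sub["gene_id"].values,
        "intergenic_distance": sub["distance"].values,
    })


def _attach_ratios(out: pd.DataFrame, expr: ExpressionTable,
                   design: TIDesign) -> pd.DataFrame:
    for cond, contrast in design.mutant_vs_wt.items():
        tab = expr.contrast(contrast)
        out[f"log2_ratio_{cond}"] = \
            tab["log2fc"].reindex(out["down_gene"]).values
    return out


def select_ti_up(contexts_or_pairs, expr: ExpressionTable,
                 design: TIDesign | None = None, d_max: int = 600,
                 up_fc_min: float = 2.0, up_padj_max: float = 0.05,
                 nde_fc_max: float = 1.5, nde_p_min: float = 0.2,
                 preexist_p: float = 0.05) -> pd.DataFrame:
    """TI induction test pairs: upstream light-upregulated vs not-DE arms.

    From tandem pairs closer than ``d_max``, the up-regulated arm keeps
    pairs whose upstream gene passes fold-change > up_fc_min (strict) and
    padj < up_padj_max in all four light-vs-dark contrasts (2 h and 4 h in
    both genotypes); the not-DE arm requires fold-change < nde_fc_max and
    padj > nde_p_min in all four.  Pairs whose downstream gene shows
    pre-existing TI in the dark (raw p < preexist_p with negative
    log2 fold-change in the mutant-vs-wt dark contrast) are removed from
    both arms.
    """
    design = design or TIDesign.default()
    design.validate(expr)
    if isinstance(contexts_or_pairs, pd.DataFrame) and \
            "up_gene" in contexts_or_pairs.columns:
        pairs = contexts_or_pairs[
            contexts_or_pairs["intergenic_distance"] < d_max]
    else:
        pairs = tandem_pairs(contexts_or_pairs, d_max)
    lfc_up_min = math.log2(up_fc_min)
    lfc_nde_max = math.log2(nde_fc_max)

    up_ok = pd.Series(True, index=pairs.index)
    nde_ok = pd.Series(True, index=pairs.index)
    for key, contrast in design.light_vs_dark.items():
        tab = expr.contrast(contrast)
        lfc = tab["log2fc"].reindex(pairs["up_gene"]).values
        padj = tab["padj"].reindex(pairs["up_gene"]).values
        up_ok &= (lfc > lfc_up_min) & (padj < up_padj_max)
        nde_ok &= (np.abs(lfc) < lfc_nde_max) & (padj > nde_p_min)

    dark = expr.contrast(design.mutant_vs_wt["dark"])
    p_dark = dark["pvalue"].reindex(pairs["down_gene"]).values
    lfc_dark = dark["log2fc"].reindex(pairs["down_gene"]).values
    preexisting = (p_dark < preexist_p) & (lfc_dark < 0)

    out = pairs.copy()
    out["arm"] = np.where(up_ok, "up_regulated",
                          np.where(nde_ok, "up_not_de", "none"))
    out["passes_preexisting_TI_filter"] = ~preexisting
    out = out[(out["arm"] != "none") & out["passes_preexisting_TI_filter"]]
    out = _attach_ratios(out.reset_index(drop=True), expr, design)
    return out


def select_ti_relief(contexts_or_pairs, expr: ExpressionTable,
                     design: TIDesign | None = None, d_max: int = 600,
                     down_fc_min: float = 1.5, down_padj_max: float = 0.05,
                     nde_fc_max: float = 1.5, nde_p_min: float = 0.1,
                     ti_evidence_p: float = 0.05) -> pd.DataFrame:
    """TI relief pairs: downstream gene TI-affected in the dark.

    Keeps pairs whose downstream gene shows evidence of TI in the dark
    (raw p < ti_evidence_p, negative mutant-vs-wt log2FC).  The
    down-regulated arm requires the upstream gene light-downregulated
    (fold-change > down_fc_min downward, padj < down_padj_max) in both
    genotypes at 2 h or at 4 h; the not-DE arm requires fold-change
    < nde_fc_max and padj > nde_p_min in all four light contrasts.
    """
    design = design or TIDesign.default()
    design.validate(expr)
    if isinstance(contexts_or_pairs, pd.DataFrame) and \
            "up_gene" in contexts_or_pairs.columns:
        pairs = contexts_or_pairs[
            contexts_or_pairs["intergenic_distance"] < d_max]
    else:
        pairs = tandem_pairs(contexts_or_pairs, d_max)

    dark = expr.contrast(design.mutant_vs_wt["dark"])
    p_dark = dark["pvalue"].reindex(pairs["down_gene"]).values
    lfc_dark = dark["log2fc"].reindex(pairs["down_gene"]).values
    has_ti = (p_dark < ti_evidence_p) & (lfc_dark < 0)

    lfc_dn_min = math.log2(down_fc_min)
    lfc_nde_max = math.log2(nde_fc_max)
    per_time_ok = {}
    nde_ok = pd.Series(True, index=pairs.index)
    for (genotype, time), contrast in design.light_vs_dark.items():
        tab = expr.contrast(contrast)
        lfc = tab["log2fc"].reindex(pairs["up_gene"]).values
        padj = tab["padj"].reindex(pairs["up_gene"]).values
        down_pass = (lfc < -lfc_dn_min) & (padj < down_padj_max)
        per_time_ok.setdefault(time, []).append(down_pass)
        nde_ok &= (np.abs(lfc) < lfc_nde_max) & (padj > nde_p_min)
    down_arm = np.zeros(len(pairs), dtype=bool)
    for time, passes in per_time_ok.items():
        down_arm |= np.logical_and.reduce(passes)

    out = pairs.copy()
    out["arm"] = np.where(down_arm, "up_downregulated",
                          np.where(nde_ok, "up_not_de", "none"))
    out = out[(out["arm"] != "none") & has_ti]
    out = _attach_ratios(out.reset_index(drop=True), expr, design)
    return out


def ti_ratio_tests(selection: pd.DataFrame,
                   alternative: str = "two_sided") -> pd.DataFrame:
    """Wilcoxon signed-rank of downstream log2(mutant/wt): dark vs light.

    One paired test per arm and light time point, on the change in the
    downstream gene's mutant/wild-type ratio between dark and light.
    """
    rows = []
    for arm, sub in selection.groupby("arm"):
        for cond in ("light2", "light4"):
            d = (sub[f"log2_ratio_{cond}"] -
                 sub["log2_ratio_dark"]).dropna().values
            row = {"arm": arm, "comparison": f"{cond}_vs_dark", "n": len(d),
                   "median_delta": float(np.median(d)) if len(d) else np.nan}
            if len(d) < 2:
                row.update(statistic=np.nan, p=np.nan)
            else:
                res = stats.wilcoxon_signed_rank(d, alternative)
                row.update(statistic=res.statistic, p=res.p)
            rows.append(row)
    out = pd.DataFrame(rows)
    out["padj"] = stats.bh_adjust(out["p"].values)
    return out


def light_induced_distance_analysis(light_up_genes, contexts: pd.DataFrame,
                                    ratios: pd.DataFrame,
                                    distance_bins=(600, 1200),
                                    min_per_side: int = 5,
                                    alternative: str = "two_sided"
                                    ) -> pd.DataFrame:
    """Same- vs opposite-strand upstream context of light-induced genes.

    Genes up-regulated by light are binned by the distance from their TSS
    to the nearest border of their upstream gene (<600, 600-1200, >1200 bp
    by default) and by upstream orientation (S/O).  Per condition and bin,
    the downstream genes' log2(mutant/wt) ratios of S vs O genes are
    compared by Mann-Whitney U, BH-adjusted over all bins x conditions.

    ``ratios``: DataFrame indexed by gene_id, one column per condition.
    """
    light_up = set(light_up_genes)
    up = contexts[(contexts["side"] == "upstream")
                  & contexts["gene_id"].isin(light_up)
                  & contexts["neighbor_id"].notna()].copy()
    edges = [0] + list(distance_bins) + [float("inf")]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"<{hi:g}" if lo == 0 else
                      (f">{lo:g}" if math.isinf(hi) else f"{lo:g}-{hi:g}"))
    up["bin"] = pd.cut(up["distance"], bins=edges, labels=labels,
                       right=False, include_lowest=True)
    rows = []
    for cond in ratios.columns:
        vals = ratios[cond]
        for label in labels:
            sub = up[up["bin"] == label]
            s_genes = sub[sub["orientation"] == "same_strand"]["gene_id"]
            o_genes = sub[sub["orientation"] == "opposite_strand"]["gene_id"]
            s = vals.reindex(s_genes).dropna().values
            o = vals.reindex(o_genes).dropna().values
            row = {"condition": cond, "distance_bin": label,
                   "n_same": len(s), "n_opposite": len(o),
                   "median_same": float(np.median(s)) if len(s) else np.nan,
                   "median_opposite": float(np.median(o)) if len(o) else np.nan}
            if len(s) < min_per_side or len(o) < min_per_side:
                row.update(U=np.nan, p=np.nan)
            else:
                res = stats.mann_whitney_u(s, o, alternative)
                row.update(U=res.statistic, p=res.p)
            rows.append(row)
    out = pd.DataFrame(rows)
    out["padj"] = stats.bh_adjust(out["p"].values)
    return out
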