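"""Context statistics, loop enrichment, and TI selection procedures."""

import math

import numpy as np
import pandas as pd
import pytest

from pausepoint import annotation as ann
from pausepoint import interference as tf
from pausepoint import synthetic
from pausepoint.annotation import ExpressionTable
from pausepoint.interference import RegulatedGeneSets, TIDesign


def test_regulated_sets_must_be_disjoint():
    with pytest.raises(ValueError):
        RegulatedGeneSets({"a"}, {"a"}, set())


@pytest.fixture(scope="module")
def context_study():
    """Default-scale annotation + loops (no coverage; cheap to build)."""
    cfg = synthetic.SimulationConfig()
    genes, truth = synthetic.gen_annotation(cfg, seed=57)
    loops = synthetic.gen_loops(cfg, truth, seed=57)
    ctx = ann.contexts_frame(ann.neighbor_contexts(genes))
    return truth, loops, ctx


# --- orientation / distance / upstream expression ------------------------

def test_orientation_fractions_planted(small_study, small_contexts):
    truth = small_study.truth
    sets = RegulatedGeneSets(set(truth.protected), set(truth.repressed),
                             set())
    out = tf.orientation_fractions(sets, small_contexts,
                                   distance_bins=(float("inf"),))
    prot = out[(out.set == "protected") & (out.side == "upstream")
               & (out.orientation == "same_strand")]
    assert prot.fraction.iloc[0] == pytest.approx(
        truth.protected_tandem_fraction, abs=0.02)


def test_orientation_single_gene_divergent():
    ctx = pd.DataFrame([{
        "gene_id": "g1", "side": "upstream", "neighbor_id": "g0",
        "orientation": "opposite_strand", "distance": 100,
        "pair_class": "divergent", "overlap": False}])
    sets = RegulatedGeneSets({"g1"}, set(), set())
    out = tf.orientation_fractions(sets, ctx, distance_bins=(1000,))
    row = out[(out.set == "protected") & (out.side == "upstream")
              & (out.orientation == "same_strand")]
    assert row.fraction.iloc[0] == 0.0


def test_orientation_tight_distance_bin_gives_zero(small_study,
                                                   small_contexts):
    sets = RegulatedGeneSets(set(small_study.truth.protected), set(), set())
    out = tf.orientation_fractions(sets, small_contexts, distance_bins=(0,))
    sub = out[(out.set == "protected") & (out.fraction > 0)]
    # only abutting pairs (distance exactly 0) could survive
    assert (small_contexts.distance.dropna() > 0).all() or len(sub) >= 0
    assert out[(out.set == "protected")
               & (out.orientation == "same_strand")].fraction.max() <= 0.1


def test_distance_tests_planted_medians(small_study, small_contexts):
    truth = small_study.truth
    sets = RegulatedGeneSets(set(truth.protected), set(truth.repressed),
                             set())
    out = tf.distance_distribution_tests(sets, small_contexts)
    prot = out.set_index("set").loc["protected"]
    assert prot.median_bp == pytest.approx(truth.protected_median_distance)
    assert prot.background_median_bp == pytest.approx(
        truth.background_median_distance)
    assert prot.p < 0.05  # planted short distances differ from background


def test_distance_tests_small_set_na(small_contexts):
    sets = RegulatedGeneSets({"SYNG001"}, set(), set())
    out = tf.distance_distribution_tests(sets, small_contexts)
    assert np.isnan(out.set_index("set").loc["protected", "p"])


def test_upstream_expression_planted_boost(context_study):
    truth, _, ctx = context_study
    expr = ExpressionTable(pd.DataFrame({
        "mean_expression": truth.genes["expr_log2"],
        "basemean": np.ones(len(truth.genes)),
    }))
    sets = RegulatedGeneSets(set(truth.protected), set(truth.repressed),
                             set(truth.null_genes))
    out = tf.upstream_expression_test(sets, ctx, expr)
    row = out.set_index("comparison").loc["protected_vs_not_de"]
    assert row.median_protected > row.median_other
    assert row.p < 0.01


# --- loops ---------------------------------------------------------------

def test_loop_enrichment_known_fisher_value():
    ctx = pd.DataFrame(columns=["gene_id", "side", "neighbor_id",
                                "orientation", "distance", "pair_class",
                                "overlap"])
    universe = [f"g{i}" for i in range(8)]
    sets = RegulatedGeneSets(set(universe[:4]), set(), set())
    loops = {"g0", "g1", "g2", "g4"}   # table (3,1;1,3)
    out = tf.loop_enrichment(sets, ctx, loops, universe=universe)
    row = out.set_index("context").loc["protected"]
    assert row.p == pytest.approx(17 / 70)


def test_loop_enrichment_all_genes_loop():
    ctx = pd.DataFrame(columns=["gene_id", "side", "neighbor_id",
                                "orientation", "distance", "pair_class",
                                "overlap"])
    universe = [f"g{i}" for i in range(8)]
    sets = RegulatedGeneSets(set(universe[:4]), set(), set())
    with pytest.warns(UserWarning):
        out = tf.loop_enrichment(sets, ctx, set(universe), universe=universe)
    assert (out.p == 1.0).all()


def test_loop_enrichment_planted_context_smallest(context_study):
    truth, loops, ctx = context_study
    sets = RegulatedGeneSets(set(truth.protected), set(truth.repressed),
                             set())
    out = tf.loop_enrichment(sets, ctx, loops)
    best = out.sort_values(["padj", "p"]).iloc[0]
    assert best.context == "protected_upstream_same"


# --- TI selection --------------------------------------------------------

def _ti_fixture():
    """Six handcrafted pairs exercising every Fig-7d-style threshold."""
    pairs = pd.DataFrame({
        "up_gene": [f"u{i}" for i in range(6)],
        "down_gene": [f"d{i}" for i in range(6)],
        "intergenic_distance": [100, 200, 300, 400, 700, 150],
    })
    genes = [f"u{i}" for i in range(6)] + [f"d{i}" for i in range(6)]

    def tab(lfc, p, padj):
        return pd.DataFrame({"log2fc": lfc, "pvalue": p, "padj": padj},
                            index=genes)

    # u0, u1 up-regulated everywhere; u2, u3 not-DE; u4 up (but distance
    # 700 excluded); u5 up but its downstream d5 has pre-existing TI
    up_lfc = [1.5, 2.0, 0.1, -0.2, 1.8, 1.6]
    up_p = [0.001] * 2 + [0.8, 0.9] + [0.001, 0.001]
    up_padj = [0.01] * 2 + [0.9, 0.95] + [0.01, 0.01]
    down_zero = [0.0] * 6
    light = tab(up_lfc + down_zero, up_p + [0.5] * 6, up_padj + [0.9] * 6)
    contrasts = {name: light.copy() for name in (
        "light2_vs_dark_wt", "light4_vs_dark_wt",
        "light2_vs_dark_mut", "light4_vs_dark_mut")}
    # mutant-vs-wt: d5 pre-existing TI (p<0.05, lfc<0) in dark
    dark_lfc = [0.0] * 6 + [0.0, 0.0, 0.0, 0.0, 0.0, -1.0]
    dark_p = [0.5] * 6 + [0.5, 0.5, 0.5, 0.5, 0.5, 0.01]
    contrasts["mut_vs_wt_dark"] = tab(dark_lfc, dark_p, [0.9] * 12)
    contrasts["mut_vs_wt_light2"] = tab([0.0] * 12, [0.5] * 12, [0.9] * 12)
    contrasts["mut_vs_wt_light4"] = tab([0.0] * 12, [0.5] * 12, [0.9] * 12)
    gdf = pd.DataFrame({"mean_expression": 0.0, "basemean": 10.0},
                       index=genes)
    return pairs, ExpressionTable(gdf, contrasts)


def test_select_ti_up_manual_walk():
    pairs, expr = _ti_fixture()
    out = tf.select_ti_up(pairs, expr)
    arms = out.groupby("arm")["up_gene"].apply(set).to_dict()
    assert arms["up_regulated"] == {"u0", "u1"}
    assert arms["up_not_de"] == {"u2", "u3"}
    assert "u4" not in set(out.up_gene)   # distance 700 >= 600
    assert "u5" not in set(out.up_gene)   # pre-existing TI filtered


def test_select_ti_up_boundary_strictness():
    pairs, expr = _ti_fixture()
    # fc exactly 2 (log2fc = 1) must be excluded from the up arm
    for name in ("light2_vs_dark_wt", "light4_vs_dark_wt",
                 "light2_vs_dark_mut", "light4_vs_dark_mut"):
        expr.contrasts[name].loc["u0", "log2fc"] = 1.0
    out = tf.select_ti_up(pairs, expr)
    assert "u0" not in set(out[out.arm == "up_regulated"].up_gene)
    # pre-existing TI p exactly 0.05 is kept (strict <)
    pairs2, expr2 = _ti_fixture()
    expr2.contrasts["mut_vs_wt_dark"].loc["d5", "pvalue"] = 0.05
    out2 = tf.select_ti_up(pairs2, expr2)
    assert "u5" in set(out2.up_gene)


def test_select_ti_relief_manual_walk():
    pairs, expr = _ti_fixture()
    # give d0 evidence of TI in the dark; u0 light-downregulated
    expr.contrasts["mut_vs_wt_dark"].loc["d0", ["log2fc", "pvalue"]] = \
        [-0.8, 0.01]
    for name in ("light2_vs_dark_wt", "light2_vs_dark_mut"):
        expr.contrasts[name].loc["u0", ["log2fc", "padj"]] = [-1.0, 0.01]
    out = tf.select_ti_relief(pairs, expr)
    assert set(out.up_gene) == {"u0"}
    assert out.iloc[0].arm == "up_downregulated"
    # downstream dark p exactly 0.05 -> excluded (strict <)
    expr.contrasts["mut_vs_wt_dark"].loc["d0", "pvalue"] = 0.05
    assert len(tf.select_ti_relief(pairs, expr)) == 0


def test_ti_ratio_tests_sign_enumeration():
    sel = pd.DataFrame({
        "arm": "up_regulated", "up_gene": ["u1", "u2", "u3"],
        "down_gene": ["d1", "d2", "d3"],
        "log2_ratio_dark": [0.0, 0.0, 0.0],
        "log2_ratio_light2": [-1.0, -2.0, -3.0],
        "log2_ratio_light4": [0.0, 0.0, 0.0],
    })
    out = tf.ti_ratio_tests(sel, alternative="less").set_index("comparison")
    assert out.loc["light2_vs_dark", "p"] == pytest.approx(1 / 8)
    assert out.loc["light4_vs_dark", "p"] >= 0.5


def test_selections_are_pure_functions():
    pairs, expr = _ti_fixture()
    a = tf.select_ti_up(pairs, expr)
    b = tf.select_ti_up(pairs, expr)
    pd.testing.assert_frame_equal(a, b)


# --- Fig-7f-style distance analysis --------------------------------------

def test_light_distance_analysis_small_bins_na():
    ctx = pd.DataFrame([{
        "gene_id": f"g{i}", "side": "upstream", "neighbor_id": "x",
        "orientation": "same_strand" if i % 2 else "opposite_strand",
        "distance": 100, "pair_class": "tandem", "overlap": False}
        for i in range(6)])
    ratios = pd.DataFrame({"dark": np.zeros(6)},
                          index=[f"g{i}" for i in range(6)])
    out = tf.light_induced_distance_analysis(
        [f"g{i}" for i in range(6)], ctx, ratios)
    assert out["p"].isna().all()   # 3 per side < min_per_side


def test_light_distance_analysis_null_calibration():
    rng = np.random.default_rng(7)
    hits = 0
    for rep in range(30):
        n = 80
        ctx = pd.DataFrame([{
            "gene_id": f"g{i}", "side": "upstream", "neighbor_id": "x",
            "orientation": rng.choice(["same_strand", "opposite_strand"]),
            "distance": rng.integers(0, 2000), "pair_class": "tandem",
            "overlap": False} for i in range(n)])
        ratios = pd.DataFrame({"light": rng.normal(0, 1, n)},
                              index=[f"g{i}" for i in range(n)])
        out = tf.light_induced_distance_analysis(
            [f"g{i}" for i in range(n)], ctx, ratios)
        if (out["padj"].dropna() < 0.05).any():
            hits += 1
    assert hits <= 3


def test_ti_ratio_power_and_control_calibration():
    """With >=100 pairs per arm, the light-dependent TI signal is
    detected in the up-regulated arm while the not-DE arm stays null."""
    cfg = synthetic.SimulationConfig()
    cfg.n_genes = 1200
    up_hits = ctrl_ok = 0
    ctrl_ps = []
    n_seeds = 8
    for seed in range(n_seeds):
        genes, truth = synthetic.gen_annotation(cfg, seed=900 + seed)
        expr = synthetic.gen_de_tables(cfg, genes, truth, seed=900 + seed)
        ctx = ann.contexts_frame(ann.neighbor_contexts(genes))
        sel = tf.select_ti_up(ctx, expr)
        arms = sel.groupby("arm").size()
        assert arms.get("up_regulated", 0) >= 50
        res = tf.ti_ratio_tests(sel).set_index(["arm", "comparison"])
        if res.loc[("up_regulated", "light2_vs_dark"), "p"] < 0.05:
            up_hits += 1
        p_ctrl = res.loc[("up_not_de", "light2_vs_dark"), "p"]
        ctrl_ps.append(p_ctrl)
        if p_ctrl > 0.1:
            ctrl_ok += 1
    assert up_hits >= n_seeds - 1
    assert ctrl_ok >= n_seeds - 2          # null p uniform: ~0.9 per seed
    assert np.median(ctrl_ps) > 0.1


def test_ti_pipeline_on_synthetic_study(small_study, small_contexts):
    """Planted light-dependent TI flows through selection and tests."""
    expr = small_study.expr
    up = tf.select_ti_up(small_contexts, expr)
    assert (up.groupby("arm").size() > 0).all()
    res = tf.ti_ratio_tests(up).set_index(["arm", "comparison"])
    if ("up_regulated", "light2_vs_dark") in res.index:
        assert res.loc[("up_regulated", "light2_vs_dark"), "median_delta"] < 0
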