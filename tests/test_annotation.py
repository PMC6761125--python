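"""Annotation parsing, neighbor contexts, peak annotation, gene sets."""

import numpy as np
import pandas as pd
import pytest

from pausepoint import annotation as ann
from pausepoint import synthetic
from pausepoint.annotation import (AnnotationError, ExpressionTable,
                                   GeneModel, Peak)

from conftest import make_gene


# --- coordinate conventions and IO ---------------------------------------

def test_gff3_coordinate_conversion(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("##gff-version 3\n"
                 "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
    (g,) = ann.load_annotation(p)
    assert (g.start, g.end, g.tss, g.tes) == (100, 200, 100, 199)


def test_bed_strand_symmetry(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\tg1\t0\t-\n")
    (g,) = ann.load_annotation(p)
    assert (g.tss, g.tes) == (199, 100)


def test_gff3_roundtrip_synthetic_fixture(tmp_path):
    cfg = synthetic.SimulationConfig()
    cfg.n_genes = 3
    genes, _ = synthetic.gen_annotation(cfg, seed=1)
    path = tmp_path / "three.gff3"
    ann.write_gff3(genes, path)
    loaded = ann.load_annotation(path)
    assert loaded == genes
    # writing again is byte-identical
    path2 = tmp_path / "again.gff3"
    ann.write_gff3(loaded, path2)
    assert path.read_text() == path2.read_text()


def test_bed12_roundtrip_preserves_span_and_exons(tmp_path):
    g = make_gene(features=[("exon", 100, 400), ("exon", 600, 1100)])
    path = tmp_path / "g.bed"
    ann.write_bed12([g], path)
    (back,) = ann.load_annotation(path)
    assert (back.start, back.end, back.strand) == (g.start, g.end, g.strand)
    assert back.exons() == g.exons()


def test_malformed_and_invalid_records_rejected(tmp_path):
    bad = tmp_path / "bad.gff3"
    bad.write_text("chr1\tsrc\tgene\t101\n")
    with pytest.raises(AnnotationError, match="bad.gff3:1"):
        ann.load_annotation(bad)
    rev = tmp_path / "rev.gff3"
    rev.write_text("chr1\tsrc\tgene\t200\t100\t.\t+\t.\tID=g1\n")
    with pytest.raises(AnnotationError):
        ann.load_annotation(rev)
    dup = tmp_path / "dup.gff3"
    dup.write_text("chr1\ts\tgene\t1\t10\t.\t+\t.\tID=g1\n"
                   "chr1\ts\tgene\t20\t30\t.\t+\t.\tID=g1\n")
    with pytest.raises(AnnotationError, match="duplicate"):
        ann.load_annotation(dup)
    with pytest.raises(AnnotationError):
        GeneModel("g", "chr1", 10, 10, "+")


# --- neighbor contexts ---------------------------------------------------

def test_tandem_distance_is_border_gap():
    up = make_gene("up", start=0, end=1000, strand="+")
    down = make_gene("down", start=1244, end=2500, strand="+")
    ctxs = {(c.gene_id, c.side): c
            for c in ann.neighbor_contexts([up, down])}
    c = ctxs[("down", "upstream")]
    assert c.pair_class == "tandem"
    assert c.intergenic_distance == 244
    # symmetry: up's downstream context mirrors it
    c2 = ctxs[("up", "downstream")]
    assert c2.neighbor_id == "down"
    assert c2.pair_class == "tandem"
    assert c2.intergenic_distance == 244


def test_divergent_and_convergent_classification():
    left = make_gene("l", start=0, end=1000, strand="-")
    right = make_gene("r", start=1500, end=2500, strand="+")
    ctxs = {(c.gene_id, c.side): c
            for c in ann.neighbor_contexts([left, right])}
    assert ctxs[("r", "upstream")].pair_class == "divergent"
    assert ctxs[("l", "upstream")].pair_class == "divergent"
    # tail-to-tail
    a = make_gene("a", start=0, end=1000, strand="+")
    b = make_gene("b", start=1500, end=2500, strand="-")
    ctxs = {(c.gene_id, c.side): c for c in ann.neighbor_contexts([a, b])}
    assert ctxs[("a", "downstream")].pair_class == "convergent"
    assert ctxs[("b", "downstream")].pair_class == "convergent"


def test_overlapping_pair_flagged_distance_zero():
    a = make_gene("a", start=0, end=1200, strand="+")
    b = make_gene("b", start=1000, end=2200, strand="+")
    ctxs = {(c.gene_id, c.side): c for c in ann.neighbor_contexts([a, b])}
    c = ctxs[("b", "upstream")]
    assert c.overlap and c.intergenic_distance == 0


def test_unsorted_input_rejected():
    a = make_gene("a", start=2000, end=3000)
    b = make_gene("b", start=0, end=1000)
    with pytest.raises(AnnotationError, match="sorted"):
        ann.neighbor_contexts([a, b])


def test_max_distance_drops_far_neighbors():
    a = make_gene("a", start=0, end=1000)
    b = make_gene("b", start=5000, end=6000)
    ctxs = {(c.gene_id, c.side): c
            for c in ann.neighbor_contexts([a, b], max_distance=2000)}
    assert ctxs[("b", "upstream")].neighbor_id is None


def test_nested_gene_skipped_as_neighbor():
    host = make_gene("host", start=0, end=5000, strand="+")
    nested = make_gene("nested", start=1000, end=2000, strand="+")
    right = make_gene("right", start=6000, end=7000, strand="+")
    ctxs = {(c.gene_id, c.side): c
            for c in ann.neighbor_contexts([host, nested, right])}
    assert ctxs[("right", "upstream")].neighbor_id == "host"


def test_context_symmetry_on_synthetic_genome(small_study, small_contexts):
    """A downstream-tandem partner sees the focal gene upstream, same gap."""
    ctx = small_contexts
    up = ctx[(ctx.side == "upstream") & (ctx.pair_class == "tandem")]
    down = ctx[(ctx.side == "downstream") & (ctx.pair_class == "tandem")]
    down_map = {(r.gene_id, r.neighbor_id): r.distance
                for r in down.itertuples()}
    for r in up.itertuples():
        assert down_map[(r.neighbor_id, r.gene_id)] == r.distance


def test_planted_tandem_fraction_recovered_exactly():
    cfg = synthetic.SimulationConfig()
    cfg.n_genes = 100
    cfg.fraction_tandem = 0.6
    cfg.protected_fraction = 0.0
    genes, truth = synthetic.gen_annotation(cfg, seed=5)
    ctx = ann.contexts_frame(ann.neighbor_contexts(genes))
    up = ctx[(ctx.side == "upstream") & ctx.neighbor_id.notna()]
    frac = (up.pair_class == "tandem").mean()
    assert frac == pytest.approx(truth.background_tandem_fraction)


# --- peak annotation -----------------------------------------------------

@pytest.fixture(scope="module")
def peak_genes():
    ga = GeneModel("ga", "chr1", 1000, 3000, "+", (
        ("five_prime_UTR", 1000, 1150), ("exon", 1000, 1800),
        ("exon", 2100, 3000), ("three_prime_UTR", 2800, 3000)))
    gb = GeneModel("gb", "chr1", 3200, 5000, "+")
    return [ga, gb]


def test_promoter_precedence_beats_downstream(peak_genes):
    # 100 bp upstream of gb's TSS and 101 bp downstream of ga's TES
    pk = Peak("chr1", 3090, 3110, 3100, name="p")
    (res,) = ann.annotate_peaks([pk], peak_genes)
    assert res.category == "promoter" and res.assigned_gene == "gb"


def test_exon_only_hit(peak_genes):
    pk = Peak("chr1", 1500, 1520, 1510, name="p")
    (res,) = ann.annotate_peaks([pk], peak_genes)
    assert res.category == "exon"


def test_handcrafted_peaks_all_categories(peak_genes):
    cases = [
        (900, "promoter"),             # 100 bp upstream of ga TSS
        (3095, "promoter"),            # gb promoter wins over ga downstream
        (5100, "immediate_downstream"),  # 101 bp after gb TES
        (1100, "five_prime_UTR"),
        (2900, "three_prime_UTR"),
        (1700, "exon"),
        (1900, "intron"),
        (4000, "exon"),                # featureless gene body counts exonic
        (8000, "intergenic"),
        (700, "intergenic"),           # exactly 300 bp from ga start
    ]
    peaks = [Peak("chr1", s - 5, s + 5, s, name=f"p{i}")
             for i, (s, _) in enumerate(cases)]
    res = ann.annotate_peaks(peaks, peak_genes)
    got = [r.category for r in res]
    assert got == [c for _, c in cases]


def test_annotate_category_frequencies_sum_to_one(small_study):
    genes = small_study.genes
    rng = np.random.default_rng(0)
    chrom_len = small_study.truth.chrom_len
    pos = rng.integers(0, chrom_len, 300)
    peaks = [Peak(genes[0].chrom, p, p + 1, p, name=f"r{i}")
             for i, p in enumerate(pos)]
    res = ann.annotate_peaks(peaks, genes)
    assert len(res) == 300
    counts = pd.Series([r.category for r in res]).value_counts()
    assert counts.sum() == 300


def test_classifier_agrees_with_annotate_peaks(small_study):
    """Vectorized null classifier matches the per-peak precedence walk."""
    genes = small_study.genes
    chrom = genes[0].chrom
    rng = np.random.default_rng(1)
    pos = np.sort(rng.integers(0, small_study.truth.chrom_len, 500))
    peaks = [Peak(chrom, p, p + 1, p, name=str(p)) for p in pos]
    per_peak = [r.category for r in ann.annotate_peaks(peaks, genes)]
    vec = ann.classify_positions({chrom: pos}, genes)[chrom]
    assert [ann.PEAK_CATEGORIES[i] for i in vec] == per_peak


def test_summit_outside_bounds_rejected(peak_genes):
    pk = Peak("chr1", 99990, 100010, 100000, name="p")
    with pytest.raises(AnnotationError, match="bounds"):
        ann.annotate_peaks([pk], peak_genes, chrom_sizes={"chr1": 50000})


def test_enrichment_extreme_promoter_forcing(peak_genes):
    peaks = [Peak("chr1", 900, 930, 905 + i, name=f"p{i}") for i in range(20)]
    res = ann.random_position_enrichment(
        peaks, peak_genes, {"chr1": 20000}, n_samples=500, seed=0)
    prom = res.set_index("category").loc["promoter"]
    assert prom.observed_fraction == 1.0
    assert prom.empirical_p <= 2 / 501


def test_enrichment_null_calibration(peak_genes):
    rng = np.random.default_rng(2)
    hits = 0
    for rep in range(20):
        pos = rng.integers(0, 20000, 40)
        peaks = [Peak("chr1", p, p + 1, p, name=f"p{i}")
                 for i, p in enumerate(pos)]
        res = ann.random_position_enrichment(
            peaks, peak_genes, {"chr1": 20000}, n_samples=400, seed=rep)
        if (res.empirical_p < 0.01).any():
            hits += 1
    assert hits <= 3


def test_enrichment_rejects_bad_sample_count(peak_genes):
    pk = Peak("chr1", 900, 920, 910, name="p")
    with pytest.raises(ValueError):
        ann.random_position_enrichment([pk], peak_genes, {"chr1": 20000},
                                       n_samples=0)


# --- expression groups and control selection -----------------------------

def test_expression_groups_even_split():
    expr = pd.Series(np.arange(18.0), index=[f"g{i}" for i in range(18)])
    groups = ann.expression_groups(expr, 9)
    assert sorted(groups.value_counts()) == [2] * 9
    assert set(groups) == set(range(1, 10))


def test_expression_groups_degenerate_ties():
    expr = pd.Series(np.ones(20), index=[f"g{i}" for i in range(20)])
    with pytest.warns(UserWarning):
        groups = ann.expression_groups(expr, 5)
    assert groups.nunique() == 1


def test_expression_groups_partition(small_study):
    expr = small_study.truth.genes["expr_log2"]
    groups = ann.expression_groups(expr, 9)
    assert len(groups) == len(expr)
    assert groups.notna().all()


def _toy_expression_table(rng, n=200, contrasts=("c1", "c2")):
    idx = [f"g{i}" for i in range(n)]
    genes = pd.DataFrame({
        "mean_expression": rng.normal(3, 1.5, n),
        "basemean": rng.uniform(1, 1000, n),
    }, index=idx)
    tabs = {}
    for c in contrasts:
        p = rng.uniform(size=n)
        tabs[c] = pd.DataFrame({
            "log2fc": rng.normal(0, 0.3, n), "pvalue": p,
            "padj": np.minimum(1, p * 1.5)}, index=idx)
    return ExpressionTable(genes, tabs)


def test_not_de_selection_matches_brute_force():
    rng = np.random.default_rng(3)
    expr = _toy_expression_table(rng)
    got = ann.select_not_de_controls(expr, ["c1", "c2"])
    want = []
    for g in expr.genes.index:
        ok = 3 < expr.genes.loc[g, "basemean"] < 1e5
        for c in ("c1", "c2"):
            row = expr.contrasts[c].loc[g]
            ok &= row.pvalue > 0.45 and abs(row.log2fc) < 0.25
        if ok:
            want.append(g)
    assert got == sorted(want)


def test_not_de_single_contrast_failure_excludes():
    idx = ["g1"]
    genes = pd.DataFrame({"mean_expression": [3.0], "basemean": [100.0]},
                         index=idx)
    mk = lambda p: pd.DataFrame(
        {"log2fc": [0.1], "pvalue": [p], "padj": [min(1, p * 2)]}, index=idx)
    expr = ExpressionTable(genes, {"a": mk(0.5), "b": mk(0.5),
                                   "c": mk(0.5), "d": mk(0.44)})
    assert ann.select_not_de_controls(expr, ["a", "b", "c"]) == ["g1"]
    assert ann.select_not_de_controls(expr, ["a", "b", "c", "d"]) == []
    with pytest.raises(KeyError):
        ann.select_not_de_controls(expr, ["missing"])


def test_matched_controls_deterministic_and_matching():
    rng = np.random.default_rng(4)
    n = 2000
    idx = [f"g{i}" for i in range(n)]
    genes = pd.DataFrame({
        "mean_expression": np.concatenate([
            rng.normal(5, 1, n // 2),      # reference-like candidates
            rng.normal(3, 1, n // 2)]),    # shifted candidates
        "basemean": np.ones(n)}, index=idx)
    expr = ExpressionTable(genes, {})
    reference = idx[: n // 4]
    candidates = idx[n // 4:]
    sel = ann.select_expression_matched_controls(
        candidates, reference, expr, n=300, seed=9)
    sel2 = ann.select_expression_matched_controls(
        candidates, reference, expr, n=300, seed=9)
    assert sel == sel2
    from pausepoint import stats
    ref_e = genes.loc[reference, "mean_expression"]
    d_matched = stats.ks_two_sample(
        genes.loc[sel, "mean_expression"], ref_e).statistic
    d_unmatched = stats.ks_two_sample(
        genes.loc[candidates, "mean_expression"], ref_e).statistic
    assert d_matched < d_unmatched
    with pytest.raises(ValueError):
        ann.select_expression_matched_controls(
            candidates[:10], reference, expr, n=300)


def test_matched_controls_self_matching_proportions():
    rng = np.random.default_rng(5)
    idx = [f"g{i}" for i in range(1000)]
    genes = pd.DataFrame({"mean_expression": rng.normal(4, 1, 1000),
                          "basemean": np.ones(1000)}, index=idx)
    expr = ExpressionTable(genes, {})
    sel = ann.select_expression_matched_controls(
        idx, idx, expr, n=500, n_bins=10, seed=1)
    assert len(sel) == 500
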