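"""Gene annotations, neighbor contexts, peak annotation and gene sets.

Internal coordinates are 0-based half-open throughout (BED convention);
GFF3's 1-based closed coordinates are converted on read and write.  The
TSS is the first transcribed base and the TES the last one, both given
as 0-based positions (start / end-1 depending on strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import stats

FEATURE_KINDS = ("five_prime_UTR", "three_prime_UTR", "exon", "intron")

PEAK_CATEGORIES = (
    "promoter",
    "immediate_downstream",
    "five_prime_UTR",
    "three_prime_UTR",
    "exon",
    "intron",
    "intergenic",
)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """One gene: location, strand, optional sub-features, expression class."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    features: tuple = ()  # (kind, start, end) 0-based half-open
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.end <= self.start:
            raise AnnotationError(
                f"{self.gene_id}: end ({self.end}) <= start ({self.start})")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        for kind, s, e in self.features:
            if kind not in FEATURE_KINDS:
                raise AnnotationError(f"{self.gene_id}: bad feature kind {kind}")
            if not (self.start <= s < e <= self.end):
                raise AnnotationError(
                    f"{self.gene_id}: feature {kind} [{s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def exons(self):
        return [(s, e) for k, s, e in self.features if k == "exon"]

    def introns(self):
        """Gene span minus exons (used when introns are not explicit)."""
        explicit = [(s, e) for k, s, e in self.features if k == "intron"]
        if explicit:
            return explicit
        ex = sorted(self.exons())
        if not ex:
            return []
        out = []
        pos = self.start
        for s, e in ex:
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < self.end:
            out.append((pos, self.end))
        return out


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise AnnotationError(
                f"peak {self.name}: summit {self.summit} outside [{self.start},{self.end})")


@dataclass(frozen=True)
class NeighborContext:
    """Nearest neighbor on one (strand-relative) side of a focal gene."""

    gene_id: str
    side: str                 # upstream | downstream
    neighbor_id: str | None
    orientation: str | None   # same_strand | opposite_strand
    intergenic_distance: int | None
    pair_class: str | None    # tandem | divergent | convergent
    overlap: bool = False


@dataclass(frozen=True)
class FeatureAnnotation:
    peak_name: str
    category: str
    assigned_gene: str | None


@dataclass
class ExpressionTable:
    """Per-gene expression summaries plus per-contrast DE results.

    ``genes``: DataFrame indexed by gene_id with columns
    ``mean_expression`` (log2 RPKM-like) and ``basemean``.
    ``contrasts``: contrast name -> DataFrame indexed by gene_id with
    columns ``log2fc``, ``pvalue``, ``padj``.
    """

    genes: pd.DataFrame
    contrasts: dict = field(default_factory=dict)

    def contrast(self, name: str) -> pd.DataFrame:
        if name not in self.contrasts:
            raise KeyError(f"missing contrast {name!r}")
        return self.contrasts[name]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _parse_gff3_attrs(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def load_annotation(path, biotype_filter: str | None = None):
    """Load GFF3 or BED6/BED12 gene annotations as sorted GeneModels.

    Format is detected from the file extension (``.gff``/``.gff3`` vs
    ``.bed``).  Duplicate gene_ids are rejected; malformed records raise
    with the offending line number.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        genes = _load_gff3(path, biotype_filter)
    elif path.endswith(".bed"):
        genes = _load_bed(path)
    else:
        raise AnnotationError(f"cannot infer annotation format from {path}")
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def _load_gff3(path, biotype_filter):
    gene_rows = {}
    children = {}
    order = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from None
            if end_i < start_i:
                raise AnnotationError(f"{path}:{lineno}: end < start")
            a = _parse_gff3_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise AnnotationError(f"{path}:{lineno}: gene without ID")
                biotype = a.get("biotype", "protein_coding")
                gene_rows[gid] = (chrom, start_i - 1, end_i, strand, biotype)
                order.append(gid)
            elif ftype in FEATURE_KINDS:
                parent = a.get("Parent")
                if parent is None:
                    continue
                children.setdefault(parent, []).append(
                    (ftype, start_i - 1, end_i))
    genes = []
    for gid in order:
        chrom, s, e, strand, biotype = gene_rows[gid]
        if biotype_filter and biotype != biotype_filter:
            continue
        feats = tuple(sorted(children.get(gid, []), key=lambda f: (f[1], f[2])))
        genes.append(GeneModel(gid, chrom, s, e, strand, feats, biotype))
    return genes


def _load_bed(path):
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AnnotationError(f"{path}:{lineno}: need >= 6 BED columns")
            chrom, start, end, name, _, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from None
            feats = []
            if len(parts) >= 12:
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise AnnotationError(f"{path}:{lineno}: bad BED12 blocks")
                for bs, sz in zip(starts, sizes):
                    feats.append(("exon", s + bs, s + bs + sz))
            genes.append(GeneModel(name, chrom, s, e, strand, tuple(feats)))
    return genes


def write_gff3(genes, path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write("\t".join([g.chrom, "pausepoint", "gene",
                                str(g.start + 1), str(g.end), ".",
                                g.strand, ".", attrs]) + "\n")
            for kind, s, e in g.features:
                fh.write("\t".join([
                    g.chrom, "pausepoint", kind, str(s + 1), str(e), ".",
                    g.strand, ".",
                    f"ID={g.gene_id}.{kind}.{s};Parent={g.gene_id}"]) + "\n")


def write_bed12(genes, path):
    with open(path, "w") as fh:
        for g in genes:
            ex = sorted(g.exons()) or [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in ex)
            starts = ",".join(str(s - g.start) for s, e in ex)
            fh.write("\t".join([
                g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                str(g.start), str(g.end), "0", str(len(ex)), sizes, starts,
            ]) + "\n")


def load_narrowpeak(path):
    """Read a narrowPeak-style BED (10 columns, summit offset in col 10)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise AnnotationError(f"{path}:{lineno}: need 10 columns")
            chrom, start, end, name, score = parts[:5]
            offset = int(parts[9])
            s, e = int(start), int(end)
            peaks.append(Peak(chrom, s, e, s + offset, float(score), name))
    return peaks


# ---------------------------------------------------------------------------
# Neighbor contexts
# ---------------------------------------------------------------------------

def _check_sorted(genes):
    key = [(g.chrom, g.start) for g in genes]
    if key != sorted(key):
        raise AnnotationError("genes must be sorted by (chrom, start)")


def _contains(a: GeneModel, b: GeneModel) -> bool:
    return a.start <= b.start and b.end <= a.end


def neighbor_contexts(genes, max_distance: int | None = None):
    """Nearest-neighbor context on both strand-relative sides of each gene.

    The neighbor on each genomic side is the gene with the nearest border,
    skipping fully nested gene pairs.  Left/right are relabelled
    upstream/downstream according to the focal gene's strand; tandem pairs
    are same-strand, a head-to-head upstream pair is divergent and a
    tail-to-tail downstream pair convergent.  The intergenic distance is
    the half-open border gap (0 with ``overlap=True`` for overlapping
    pairs).
    """
    _check_sorted(genes)
    contexts = []
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        n = len(chrom_genes)
        ends = [g.end for g in chrom_genes]
        prefix_max_end = np.maximum.accumulate(ends)
        for i, g in enumerate(chrom_genes):
            # left: candidate maximizing end, skipping containment
            left = None
            j = i - 1
            while j >= 0:
                cand = chrom_genes[j]
                if not (_contains(cand, g) or _contains(g, cand)):
                    if left is None or cand.end > left.end:
                        left = cand
                if left is not None and prefix_max_end[j] <= left.end:
                    break
                j -= 1
            # right: nearest start above, skipping containment
            right = None
            for j in range(i + 1, n):
                cand = chrom_genes[j]
                if _contains(cand, g) or _contains(g, cand):
                    continue
                right = cand
                break
            for genomic_side, nb in (("left", left), ("right", right)):
                if g.strand == "+":
                    side = "upstream" if genomic_side == "left" else "downstream"
                else:
                    side = "downstream" if genomic_side == "left" else "upstream"
                if nb is None:
                    contexts.append(NeighborContext(
                        g.gene_id, side, None, None, None, None))
                    continue
                if genomic_side == "left":
                    gap = g.start - nb.end
                else:
                    gap = nb.start - g.end
                overlap = gap < 0
                dist = max(0, gap)
                if max_distance is not None and dist > max_distance:
                    contexts.append(NeighborContext(
                        g.gene_id, side, None, None, None, None))
                    continue
                if nb.strand == g.strand:
                    orientation, pair_class = "same_strand", "tandem"
                else:
                    orientation = "opposite_strand"
                    pair_class = "divergent" if side == "upstream" else "convergent"
                contexts.append(NeighborContext(
                    g.gene_id, side, nb.gene_id, orientation, dist,
                    pair_class, overlap))
    return contexts


def contexts_frame(contexts) -> pd.DataFrame:
    """Tidy DataFrame view of NeighborContext records."""
    return pd.DataFrame([{
        "gene_id": c.gene_id, "side": c.side, "neighbor_id": c.neighbor_id,
        "orientation": c.orientation, "distance": c.intergenic_distance,
        "pair_class": c.pair_class, "overlap": c.overlap,
    } for c in contexts])


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------

class _GeneIndex:
    """Interval indexes backing summit classification."""

    def __init__(self, genes, promoter_bp, downstream_bp, intergenic_bp):
        self.promoter_bp = promoter_bp
        self.downstream_bp = downstream_bp
        self.intergenic_bp = intergenic_bp
        self.span = {}
        self.halo = {}
        self.genes = {}
        for g in genes:
            self.genes.setdefault(g.chrom, []).append(g)
        for chrom, gs in self.genes.items():
            span = IntervalTree()
            halo = IntervalTree()
            for g in gs:
                span[g.start:g.end] = g
                halo[max(0, g.start - intergenic_bp):g.end + intergenic_bp] = g
            self.span[chrom] = span
            self.halo[chrom] = halo

    def candidates(self, chrom, pos):
        halo = self.halo.get(chrom)
        if halo is None:
            return []
        return [iv.data for iv in halo[pos]]


def _summit_category(pos, gene: GeneModel, promoter_bp, downstream_bp):
    """All (category, distance-to-anchor) pairs that one gene offers a summit."""
    out = []
    if gene.strand == "+":
        d_prom = gene.tss - pos
        d_down = pos - gene.tes
    else:
        d_prom = pos - gene.tss
        d_down = gene.tes - pos
    if 0 < d_prom < promoter_bp:
        out.append(("promoter", d_prom))
    if 0 < d_down < downstream_bp:
        out.append(("immediate_downstream", d_down))
    if gene.start <= pos < gene.end:
        in_named = False
        for kind, s, e in gene.features:
            if s <= pos < e and kind in ("five_prime_UTR", "three_prime_UTR",
                                         "exon"):
                out.append((kind, abs(pos - (s + e) // 2)))
                in_named = True
        if not in_named:
            if gene.exons():
                for s, e in gene.introns():
                    if s <= pos < e:
                        out.append(("intron", abs(pos - (s + e) // 2)))
            else:
                # gene without sub-features: body counts as exonic
                out.append(("exon", abs(pos - (gene.start + gene.end) // 2)))
    return out


def annotate_peaks(peaks, genes, promoter_bp: int = 300,
                   downstream_bp: int = 300, intergenic_bp: int = 300,
                   chrom_sizes: dict | None = None):
    """Assign each peak summit one category by fixed precedence.

    Precedence: promoter > immediate_downstream > 5'UTR > 3'UTR > exon >
    intron > intergenic (>= ``intergenic_bp`` from any gene span).  Ties
    among genes in the winning category break by smallest summit-to-anchor
    distance, then lexicographic gene_id.
    """
    index = _GeneIndex(genes, promoter_bp, downstream_bp, intergenic_bp)
    out = []
    for pk in peaks:
        if chrom_sizes is not None:
            size = chrom_sizes.get(pk.chrom)
            if size is None or not (0 <= pk.summit < size):
                raise AnnotationError(
                    f"peak {pk.name}: summit outside chromosome bounds")
        by_cat = {}
        for g in index.candidates(pk.chrom, pk.summit):
            for cat, dist in _summit_category(
                    pk.summit, g, promoter_bp, downstream_bp):
                by_cat.setdefault(cat, []).append((dist, g.gene_id))
        chosen = None
        for cat in PEAK_CATEGORIES[:-1]:
            if cat in by_cat:
                dist, gid = min(by_cat[cat])
                chosen = FeatureAnnotation(pk.name, cat, gid)
                break
        if chosen is None:
            chosen = FeatureAnnotation(pk.name, "intergenic", None)
        out.append(chosen)
    return out


def _category_intervals(genes, promoter_bp, downstream_bp):
    """Per-category merged interval arrays for vectorized classification."""
    cats = {c: [] for c in PEAK_CATEGORIES[:-1]}
    spans = []
    for g in genes:
        if g.strand == "+":
            cats["promoter"].append((g.chrom, g.tss - promoter_bp + 1, g.tss))
            cats["immediate_downstream"].append(
                (g.chrom, g.tes + 1, g.tes + downstream_bp))
        else:
            cats["promoter"].append((g.chrom, g.tss + 1, g.tss + promoter_bp))
            cats["immediate_downstream"].append(
                (g.chrom, g.tes - downstream_bp + 1, g.tes))
        named = False
        for kind, s, e in g.features:
            if kind in ("five_prime_UTR", "three_prime_UTR", "exon"):
                cats[kind].append((g.chrom, s, e))
                named = True
        if named:
            for s, e in g.introns():
                cats["intron"].append((g.chrom, s, e))
        else:
            cats["exon"].append((g.chrom, g.start, g.end))
        spans.append((g.chrom, g.start, g.end))
    return cats, spans


def _merge(intervals):
    merged = {}
    by_chrom = {}
    for chrom, s, e in intervals:
        if e <= s:
            continue
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (np.array([s for s, _ in out]),
                         np.array([e for _, e in out]))
    return merged


def _member(merged, chrom, pos):
    if chrom not in merged:
        return np.zeros(len(pos), dtype=bool)
    starts, ends = merged[chrom]
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < ends[idx[ok]]
    return res


def classify_positions(positions: dict, genes, promoter_bp: int = 300,
                       downstream_bp: int = 300, intergenic_bp: int = 300):
    """Vectorized category classification of single-bp positions.

    ``positions``: chrom -> int array.  Follows the annotate_peaks
    precedence; note that promoter/immediate_downstream use strict
    (0, window) distances (the intervals here are the closed pre-images of
    those strict windows).  Returns chrom -> array of category indexes
    into PEAK_CATEGORIES.
    """
    cats, _spans = _category_intervals(genes, promoter_bp, downstream_bp)
    merged_cats = {c: _merge(v) for c, v in cats.items()}
    out = {}
    for chrom, pos in positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        res = np.full(len(pos), len(PEAK_CATEGORIES) - 1, dtype=np.int64)
        unassigned = np.ones(len(pos), dtype=bool)
        for ci, cat in enumerate(PEAK_CATEGORIES[:-1]):
            hit = unassigned & _member(merged_cats[cat], chrom, pos)
            res[hit] = ci
            unassigned &= ~hit
        # positions matching no category are >= intergenic_bp from any
        # gene border, matching the annotate_peaks fallthrough
        out[chrom] = res
    return out


def random_position_enrichment(peaks, genes, chrom_sizes: dict,
                               n_samples: int = 10000, seed=None,
                               blacklist=None,
                               promoter_bp: int = 300,
                               downstream_bp: int = 300,
                               intergenic_bp: int = 300) -> pd.DataFrame:
    """Empirical per-category enrichment of peak summits vs random positions.

    Draws ``n_samples`` replicate sets of len(peaks) uniform single-bp
    positions over the non-blacklisted genome, classifies them with the
    annotate_peaks precedence rules and reports two-sided empirical
    p-values of the observed category fractions: p = 2*min(tail+1)/(n+1).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_samples < 100:
        warnings.warn("n_samples < 100 gives coarse empirical p-values")
    total = sum(chrom_sizes.values())
    if total <= 0:
        raise ValueError("zero-length genome")
    n_peaks = len(peaks)
    if n_peaks == 0:
        raise ValueError("no peaks given")

    anns = annotate_peaks(peaks, genes, promoter_bp, downstream_bp,
                          intergenic_bp)
    obs = np.zeros(len(PEAK_CATEGORIES))
    for a in anns:
        obs[PEAK_CATEGORIES.index(a.category)] += 1
    obs_frac = obs / n_peaks

    # allowed positions: genome minus blacklist, as concatenated offsets
    chroms = sorted(chrom_sizes)
    bl = {c: [] for c in chroms}
    for reg in (blacklist or []):
        chrom, s, e = reg.chrom, reg.start, reg.end
        if chrom in bl:
            bl[chrom].append((s, e))
    allowed_chrom, allowed_start, allowed_len = [], [], []
    for c in chroms:
        pos = 0
        for s, e in sorted(bl[c]):
            if s > pos:
                allowed_chrom.append(c)
                allowed_start.append(pos)
                allowed_len.append(s - pos)
            pos = max(pos, e)
        if pos < chrom_sizes[c]:
            allowed_chrom.append(c)
            allowed_start.append(pos)
            allowed_len.append(chrom_sizes[c] - pos)
    lens = np.array(allowed_len, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)])
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, cum[-1], size=(n_samples, n_peaks))
    seg = np.searchsorted(cum, draws, side="right") - 1
    offset = draws - cum[seg]

    null_frac = np.zeros((n_samples, len(PEAK_CATEGORIES)))
    flat_seg = seg.ravel()
    flat_off = offset.ravel()
    for ci, c in enumerate(chroms):
        pass
    by_chrom_pos = {}
    by_chrom_rep = {}
    for i, c in enumerate(allowed_chrom):
        mask = flat_seg == i
        if not mask.any():
            continue
        by_chrom_pos.setdefault(c, []).append(
            allowed_start[i] + flat_off[mask])
        by_chrom_rep.setdefault(c, []).append(np.nonzero(mask)[0] // n_peaks)
    for c in by_chrom_pos:
        pos = np.concatenate(by_chrom_pos[c])
        rep = np.concatenate(by_chrom_rep[c])
        cats = classify_positions({c: pos}, genes, promoter_bp,
                                  downstream_bp, intergenic_bp)[c]
        np.add.at(null_frac, (rep, cats), 1.0)
    null_frac /= n_peaks

    rows = []
    for ci, cat in enumerate(PEAK_CATEGORIES):
        ge = int((null_frac[:, ci] >= obs_frac[ci]).sum())
        le = int((null_frac[:, ci] <= obs_frac[ci]).sum())
        p = min(1.0, 2.0 * (min(ge, le) + 1) / (n_samples + 1))
        rows.append({
            "category": cat,
            "observed_fraction": obs_frac[ci],
            "null_mean": null_frac[:, ci].mean(),
            "empirical_p": p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def expression_groups(expression: pd.Series, n_groups: int = 9) -> pd.Series:
    """Quantile-based expression groups (1..n_groups), ties kept together.

    Genes are ranked and split into near-equal groups; all genes sharing
    an expression value land in the group of the lowest-ranked occurrence,
    which reproduces the unequal group sizes quantile grouping yields on
    tied data.
    """
    expr = expression.dropna()
    n = len(expr)
    if n_groups > n:
        raise ValueError("n_groups exceeds number of genes")
    order = np.argsort(expr.values, kind="mergesort")
    base = np.minimum(np.arange(n) * n_groups // n, n_groups - 1)
    group = np.empty(n, dtype=int)
    group[order] = base
    first_group = {}
    vals = expr.values
    for idx in order:
        v = vals[idx]
        if v not in first_group:
            first_group[v] = group[idx]
    ser = expr.map(first_group).astype(int) + 1
    if ser.nunique() < n_groups:
        warnings.warn("tied expression values left some groups empty")
    return ser


def select_not_de_controls(expr: ExpressionTable, contrasts,
                           p_min: float = 0.45, abs_lfc_max: float = 0.25,
                           basemean_min: float = 3.0,
                           basemean_max: float = 1e5):
    """Genes not differentially expressed in any listed contrast.

    Requires p > p_min and |log2FC| < abs_lfc_max in every contrast, and
    basemean strictly inside (basemean_min, basemean_max).
    """
    ok = (expr.genes["basemean"] > basemean_min) & \
         (expr.genes["basemean"] < basemean_max)
    for name in contrasts:
        tab = expr.contrast(name).reindex(expr.genes.index)
        ok &= (tab["pvalue"] > p_min) & (tab["log2fc"].abs() < abs_lfc_max)
    return sorted(expr.genes.index[ok.fillna(False)])


def select_expression_matched_controls(candidates, reference,
                                       expr: ExpressionTable, n: int = 1500,
                                       n_bins: int = 20, seed=None):
    """Expression-matched control sampling (stratified on quantile bins).

    The reference set's expression histogram over ``n_bins`` quantile bins
    defines per-bin quotas; candidates are drawn without replacement per
    bin.  Quota left unfillable in a bin is redistributed to bins with
    remaining candidates; if the candidate pool runs out a warning is
    emitted.
    """
    candidates = sorted(g for g in candidates if g in expr.genes.index)
    reference = [g for g in reference if g in expr.genes.index]
    if n > len(candidates):
        raise ValueError(f"requested {n} controls from {len(candidates)} candidates")
    ref_expr = expr.genes.loc[reference, "mean_expression"].values
    cand_expr = expr.genes.loc[candidates, "mean_expression"].values
    qs = np.quantile(ref_expr, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    ref_bin = np.clip(np.searchsorted(qs, ref_expr, side="right") - 1,
                      0, n_bins - 1)
    cand_bin = np.clip(np.searchsorted(qs, cand_expr, side="right") - 1,
                       0, n_bins - 1)
    ref_mass = np.bincount(ref_bin, minlength=n_bins) / len(reference)
    quota = np.floor(ref_mass * n).astype(int)
    remainder = ref_mass * n - quota
    short = n - quota.sum()
    for b in np.argsort(-remainder, kind="mergesort")[:short]:
        quota[b] += 1

    rng = np.random.default_rng(seed)
    candidates = np.asarray(candidates)
    chosen = []
    leftover = 0
    pools = {b: list(candidates[cand_bin == b]) for b in range(n_bins)}
    for b in range(n_bins):
        pool = pools[b]
        take = min(quota[b], len(pool))
        leftover += quota[b] - take
        if take:
            sel = rng.choice(len(pool), size=take, replace=False)
            for i in sorted(sel):
                chosen.append(pool[i])
            pools[b] = [p for i, p in enumerate(pool) if i not in set(sel)]
    if leftover:
        remaining = [g for b in range(n_bins) for g in pools[b]
                     if g not in set(chosen)]
        if len(remaining) < leftover:
            warnings.warn("candidate pool exhausted before reaching n")
        take = min(leftover, len(remaining))
        if take:
            sel = rng.choice(len(remaining), size=take, replace=False)
            chosen.extend(remaining[i] for i in sorted(sel))
    return sorted(chosen)
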