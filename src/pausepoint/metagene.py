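"""Anchored and gene-body-scaled average profiles (metagenes).

Windows are extracted strand-aware (minus-strand windows are reversed so
offsets always increase in the direction of transcription), pooled values
are winsorized on the upper side, and per-offset means carry a Gaussian
95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .coverage import CoverageTrack


@dataclass
class MetageneProfile:
    anchor: str               # TSS | TES | gene_body | region_center
    offsets: np.ndarray       # bp relative to anchor (or bin index for body)
    mean: np.ndarray
    ci_half_width: np.ndarray
    n: np.ndarray
    bin_bp: int = 1
    body_bins: int = 0        # >0 for gene-body profiles

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets,
            "mean": self.mean,
            "ci_lo": self.mean - self.ci_half_width,
            "ci_hi": self.mean + self.ci_half_width,
            "n": self.n,
        })

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def _z(ci_level: float) -> float:
    return float(special.ndtri(0.5 + ci_level / 2.0))


def _anchor_pos(gene, anchor: str) -> int:
    anchor = anchor.upper()
    if anchor == "TSS":
        return gene.tss
    if anchor == "TES":
        return gene.tes
    raise ValueError(f"unknown anchor {anchor!r}")


def extract_windows(track: CoverageTrack, genes, anchor: str,
                    window) -> np.ndarray:
    """(n_genes, width) matrix of coverage around the anchor.

    ``window`` is (lo, hi) in bp relative to the anchor along the
    direction of transcription, both inclusive.  Positions falling off
    the chromosome are NaN (they reduce the per-offset n instead of
    dropping the gene).
    """
    lo, hi = (-window, window) if np.isscalar(window) else window
    width = hi - lo + 1
    if width <= 0:
        raise ValueError("empty window")
    mat = np.full((len(genes), width), np.nan)
    offs = np.arange(lo, hi + 1)
    for i, g in enumerate(genes):
        v = track.values(g.chrom)
        a = _anchor_pos(g, anchor)
        if g.strand == "+":
            gs, ge = a + lo, a + hi + 1
            s, e = max(0, gs), min(len(v), ge)
            if e > s:
                mat[i, s - gs:e - gs] = v[s:e]
        else:
            gs, ge = a - hi, a - lo + 1
            s, e = max(0, gs), min(len(v), ge)
            if e > s:
                seg = v[s:e][::-1]
                left = ge - e      # leading offsets clipped (largest offset side)
                mat[i, left:left + (e - s)] = seg
    return mat, offs


def winsorize_upper(mat: np.ndarray, winsor_pct: float) -> np.ndarray:
    """Cap the most extreme upper ``winsor_pct`` percent of pooled values.

    ``winsor_pct=0.01`` caps at the 99.99th percentile of all finite
    values in the window set (one-sided upper winsorization).
    """
    if winsor_pct <= 0:
        return mat
    finite = mat[np.isfinite(mat)]
    if finite.size == 0:
        return mat
    cap = np.percentile(finite, 100.0 - winsor_pct)
    return np.where(np.isfinite(mat), np.minimum(mat, cap), mat)


def profile_from_matrix(mat: np.ndarray, offsets: np.ndarray,
                        anchor: str, winsor_pct: float = 0.01,
                        ci_level: float = 0.95, bin_bp: int = 1,
                        body_bins: int = 0) -> MetageneProfile:
    mat = winsorize_upper(mat, winsor_pct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n = np.isfinite(mat).sum(axis=0)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    ci = np.where(n > 1, _z(ci_level) * sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return MetageneProfile(anchor, offsets, mean, ci, n, bin_bp, body_bins)


def metagene_anchor(track: CoverageTrack, genes, anchor: str = "TSS",
                    flank_bp=2000, winsor_pct: float = 0.01,
                    ci_level: float = 0.95) -> MetageneProfile:
    """Average profile centered on TSS or TES, unbinned (1 bp resolution)."""
    if len(genes) == 0:
        raise ValueError("empty gene set")
    mat, offs = extract_windows(track, genes, anchor, flank_bp)
    return profile_from_matrix(mat, offs, anchor.upper(), winsor_pct, ci_level)


def genebody_matrix(track: CoverageTrack, genes, n_bins: int = 100,
                    flank_bp: int = 500, flank_bin_bp: int = 1):
    """Per-gene vector of [upstream flank | body % bins | downstream flank].

    The gene body is averaged in ``n_bins`` equal-fraction bins (genes
    shorter than n_bins share bases between bins); flanks are averaged in
    ``flank_bin_bp`` bins.  Offsets are flank bp (negative upstream of the
    TSS), body bin indexes 0..n_bins-1 stored as offsets 0..n_bins-1, and
    downstream flank offsets n_bins..; use ``body_bins`` to interpret.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n_flank = flank_bp // flank_bin_bp
    width = n_bins + 2 * n_flank
    mat = np.full((len(genes), width), np.nan)
    for i, g in enumerate(genes):
        v = track.values(g.chrom)
        body = v[g.start:g.end]
        if g.strand == "-":
            body = body[::-1]
        L = len(body)
        idx = np.arange(L) * n_bins // L
        sums = np.bincount(idx, weights=body, minlength=n_bins)
        cnts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            bins = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        if cnts.min() == 0:  # short gene: bins share bases
            pos = (np.arange(n_bins) + 0.5) * L / n_bins
            bins = body[np.minimum(pos.astype(int), L - 1)]
        mat[i, n_flank:n_flank + n_bins] = bins
        if n_flank == 0:
            continue

        up, _ = extract_windows(track, [g], "TSS", (-flank_bp, -1))
        dn, _ = extract_windows(track, [g], "TES", (1, flank_bp))
        if flank_bin_bp > 1:
            up = np.nanmean(up[0][: n_flank * flank_bin_bp]
                            .reshape(n_flank, flank_bin_bp), axis=1)
            dn = np.nanmean(dn[0][: n_flank * flank_bin_bp]
                            .reshape(n_flank, flank_bin_bp), axis=1)
        else:
            up, dn = up[0], dn[0]
        mat[i, :n_flank] = up
        mat[i, n_flank + n_bins:] = dn
    offsets = np.concatenate([
        np.arange(-n_flank, 0),
        np.arange(n_bins),
        np.arange(n_bins, n_bins + n_flank),
    ])
    return mat, offsets


def metagene_genebody(track: CoverageTrack, genes, n_bins: int = 100,
                      flank_bp: int = 500, flank_bin_bp: int = 1,
                      winsor_pct: float = 0.01,
                      ci_level: float = 0.95) -> MetageneProfile:
    """Length-normalized average profile over 100 gene-body bins + flanks."""
    if len(genes) == 0:
        raise ValueError("empty gene set")
    mat, offsets = genebody_matrix(track, genes, n_bins, flank_bp,
                                   flank_bin_bp)
    return profile_from_matrix(mat, offsets, "gene_body", winsor_pct,
                               ci_level, flank_bin_bp, n_bins)


def profile_argmax(profile: MetageneProfile, search_window=None) -> int:
    """Offset of the maximum mean; ties break toward the anchor then low.

    ``search_window`` is an inclusive (lo, hi) offset range.  A flat
    profile returns the anchor-proximal bound with a warning.
    """
    offs = np.asarray(profile.offsets)
    mean = np.asarray(profile.mean)
    if search_window is not None:
        lo, hi = search_window
        mask = (offs >= lo) & (offs <= hi)
        if not mask.any():
            raise ValueError("search window outside profile extent")
        offs, mean = offs[mask], mean[mask]
    ok = np.isfinite(mean)
    offs, mean = offs[ok], mean[ok]
    if len(mean) == 0:
        raise ValueError("no defined profile values in window")
    mx = mean.max()
    cand = offs[mean >= mx - 0.0]
    if len(cand) == len(offs) and len(offs) > 1:
        warnings.warn("flat profile in search window")
    order = np.lexsort((cand, np.abs(cand)))
    return int(cand[order[0]])


def occupancy_scores(track: CoverageTrack, genes, bin_bp: int = 20,
                     n_bins_side: int = 10) -> pd.Series:
    """Per-gene occupancy: summed signal at TSS +/- and TES +/- bins."""
    half = n_bins_side * bin_bp
    scores = np.zeros(len(genes))
    for anchor in ("TSS", "TES"):
        mat, _ = extract_windows(track, genes, anchor, (-half, half - 1))
        binned = np.nanmean(
            mat.reshape(len(genes), 2 * n_bins_side, bin_bp), axis=2)
        scores += np.nansum(binned, axis=1)
    return pd.Series(scores, index=[g.gene_id for g in genes])


def heatmap_matrix(track: CoverageTrack, genes, top_k: int | None = None,
                   n_bins: int = 100, flank_bp: int = 1000,
                   flank_bin_bp: int = 20):
    """Gene x bin matrix ordered by decreasing TSS/TES occupancy score.

    Ties in the score keep a stable lexicographic gene_id order.  Returns
    (DataFrame rows=genes, offsets) ready to write as TSV.
    """
    scores = occupancy_scores(track, genes, flank_bin_bp)
    if top_k is not None and top_k > len(genes):
        warnings.warn(f"top_k={top_k} exceeds gene count; using all genes")
        top_k = len(genes)
    order = sorted(range(len(genes)),
                   key=lambda i: (-scores.iloc[i], genes[i].gene_id))
    if top_k is not None:
        order = order[:top_k]
    sel = [genes[i] for i in order]
    mat, offsets = genebody_matrix(track, sel, n_bins, flank_bp, flank_bin_bp)
    df = pd.DataFrame(mat, index=[g.gene_id for g in sel], columns=offsets)
    return df, offsets
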