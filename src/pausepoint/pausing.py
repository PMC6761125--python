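"""3' pausing index: per-gene computation and condition comparisons.

The pausing index of an expressed gene (> 1 kb) is the ratio of mean
coverage in a window just downstream of the TES to mean coverage over the
gene body, computed strand-aware.  Condition comparisons use a paired
Student's t test on log2 indexes within expression groups, BH-adjusted
across all (group x antibody) tests of a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .coverage import CoverageTrack, region_density


@dataclass
class PausingRecord:
    gene_id: str
    condition: str
    antibody: str
    body_density: float
    tes_density: float
    pausing_index: float      # NaN when undefined (zero body density)
    log2_pi: float
    flags: tuple = ()

    @property
    def defined(self) -> bool:
        return math.isfinite(self.log2_pi)


def pausing_index(track: CoverageTrack, gene, tes_window_bp: int = 200,
                  body_trim=(0, 0), min_gene_len: int = 1000,
                  condition: str = "wt", antibody: str = "PolII",
                  next_gene_start: int | None = None) -> PausingRecord | None:
    """Per-gene 3' pausing index; None when the gene is below min length.

    Body = [TSS+trim0, TES-trim1) and TES window = the ``tes_window_bp``
    bases immediately downstream of the TES, both in the direction of
    transcription.  Windows running off the chromosome are truncated and
    flagged; a TES window reaching into the next gene body (when
    ``next_gene_start`` along the transcription axis is supplied) is
    computed but flagged.
    """
    if gene.length <= min_gene_len:
        return None
    flags = []
    v = track.values(gene.chrom)
    trim0, trim1 = body_trim
    if gene.strand == "+":
        body = (gene.start + trim0, gene.end - trim1)
        tes_lo, tes_hi = gene.end, gene.end + tes_window_bp
        if tes_hi > len(v):
            tes_hi = len(v)
            flags.append("tes_window_truncated")
    else:
        body = (gene.start + trim1, gene.end - trim0)
        tes_lo, tes_hi = gene.start - tes_window_bp, gene.start
        if tes_lo < 0:
            tes_lo = 0
            flags.append("tes_window_truncated")
    if body[1] <= body[0]:
        raise ValueError(f"{gene.gene_id}: body trim leaves empty region")
    if tes_hi <= tes_lo:
        raise ValueError(f"{gene.gene_id}: TES window off chromosome")
    if next_gene_start is not None:
        if gene.strand == "+" and tes_hi > next_gene_start:
            flags.append("tes_window_in_next_gene")
        if gene.strand == "-" and tes_lo < next_gene_start:
            flags.append("tes_window_in_next_gene")

    body_d = region_density(track, gene.chrom, *body)
    tes_d = region_density(track, gene.chrom, tes_lo, tes_hi)
    if body_d <= 0:
        flags.append("undefined_zero_body")
        pi = log2_pi = float("nan")
    else:
        pi = tes_d / body_d
        log2_pi = math.log2(pi) if pi > 0 else float("nan")
        if pi <= 0:
            flags.append("undefined_zero_tes")
    return PausingRecord(gene.gene_id, condition, antibody, body_d, tes_d,
                         pi, log2_pi, tuple(flags))


def pausing_table(track: CoverageTrack, genes, condition: str = "wt",
                  antibody: str = "PolII", tes_window_bp: int = 200,
                  body_trim=(0, 0), min_gene_len: int = 1000) -> pd.DataFrame:
    """Pausing records for a gene collection as a DataFrame."""
    rows = []
    for g in genes:
        rec = pausing_index(track, g, tes_window_bp, body_trim, min_gene_len,
                            condition, antibody)
        if rec is None:
            continue
        rows.append({
            "gene_id": rec.gene_id, "condition": rec.condition,
            "antibody": rec.antibody, "body_density": rec.body_density,
            "tes_density": rec.tes_density, "pausing_index": rec.pausing_index,
            "log2_pi": rec.log2_pi, "flags": ",".join(rec.flags),
        })
    return pd.DataFrame(rows)


def compare_pausing(records_a: pd.DataFrame, records_b: pd.DataFrame,
                    groups: pd.Series | dict | None = None,
                    min_pairs: int = 3) -> pd.DataFrame:
    """Paired t tests of mean log2 pausing index, per expression group.

    Records are paired by gene_id (within antibody); genes with an
    undefined index in either condition are dropped and counted.  BH
    adjustment spans all (group x antibody) tests of the call.
    """
    a = records_a.set_index("gene_id")
    b = records_b.set_index("gene_id")
    if groups is None:
        groups = pd.Series(1, index=a.index)
    elif isinstance(groups, dict):
        groups = pd.Series(groups)
    rows = []
    for antibody in sorted(set(a["antibody"]) & set(b["antibody"])):
        ai = a[a["antibody"] == antibody]
        bi = b[b["antibody"] == antibody]
        shared = ai.index.intersection(bi.index)
        la = ai.loc[shared, "log2_pi"]
        lb = bi.loc[shared, "log2_pi"]
        ok = np.isfinite(la) & np.isfinite(lb)
        n_dropped = int((~ok).sum())
        gr_all = groups.reindex(shared)
        gr = gr_all[ok]
        la, lb = la[ok], lb[ok]
        for g in sorted(gr_all.dropna().unique()):
            sel = gr == g
            xa, xb = la[sel].values, lb[sel].values
            row = {
                "group": g, "antibody": antibody, "n": int(sel.sum()),
                "n_dropped_undefined": n_dropped,
                "mean_log2_pi_a": float(xa.mean()) if len(xa) else np.nan,
                "mean_log2_pi_b": float(xb.mean()) if len(xb) else np.nan,
            }
            if sel.sum() < min_pairs:
                row.update(t=np.nan, p=np.nan, direction="NA")
            else:
                res = stats.paired_t(xb, xa)
                diff = float((xb - xa).mean())
                row.update(
                    t=res.statistic, p=res.p,
                    direction=("reduced_in_b" if diff < 0
                               else "increased_in_b" if diff > 0 else "equal"))
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = stats.bh_adjust(out["p"].values)
    return out
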