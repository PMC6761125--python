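"""Downstream displacement of 3' paused Pol II between conditions.

The population shift is the difference between the argmax offsets of two
TES-anchored average profiles computed over the same gene set; per-gene
shifts apply the same argmax rule to raw per-gene windows.  Group shifts
are tested against the all-expressed baseline with a one-sided Wilcoxon
signed-rank test, BH-adjusted across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .coverage import CoverageTrack
from .metagene import extract_windows, metagene_anchor, profile_argmax, \
    MetageneProfile


@dataclass
class ShiftEstimate:
    scope: str                # population | per_gene
    shift: int                # bp, positive = downstream in b
    offset_a: int
    offset_b: int
    gene_id: str | None = None
    antibody: str = "PolII"
    n_genes: int | None = None


def population_shift(track_a: CoverageTrack, track_b: CoverageTrack, genes,
                     window=(-1000, 1000), winsor_pct: float = 0.01,
                     ci_level: float = 0.95,
                     antibody: str = "PolII") -> ShiftEstimate:
    """Shift of the TES-anchored average-profile maximum from a to b."""
    if len(genes) < 20:
        import warnings
        warnings.warn(f"only {len(genes)} genes; population shift is noisy")
    prof_a = metagene_anchor(track_a, genes, "TES", window, winsor_pct,
                             ci_level)
    prof_b = metagene_anchor(track_b, genes, "TES", window, winsor_pct,
                             ci_level)
    off_a = profile_argmax(prof_a, window)
    off_b = profile_argmax(prof_b, window)
    return ShiftEstimate("population", off_b - off_a, off_a, off_b,
                         antibody=antibody, n_genes=len(genes))


def _row_argmax(row: np.ndarray, offsets: np.ndarray) -> int | None:
    ok = np.isfinite(row)
    if not ok.any():
        return None
    vals, offs = row[ok], offsets[ok]
    mx = vals.max()
    cand = offs[vals == mx]
    order = np.lexsort((cand, np.abs(cand)))
    return int(cand[order[0]])


def per_gene_shifts(track_a: CoverageTrack, track_b: CoverageTrack, genes,
                    window=(-1000, 1000), min_signal: float = 0.0,
                    antibody: str = "PolII") -> pd.DataFrame:
    """Per-gene argmax shifts on raw (unwinsorized) TES windows.

    Genes whose window maximum does not exceed ``min_signal`` in both
    tracks are dropped (counted in the ``n_dropped`` attribute of the
    returned frame).
    """
    mat_a, offs = extract_windows(track_a, genes, "TES", window)
    mat_b, _ = extract_windows(track_b, genes, "TES", window)
    rows = []
    n_dropped = 0
    for i, g in enumerate(genes):
        with np.errstate(invalid="ignore"):
            max_a = np.nanmax(mat_a[i]) if np.isfinite(mat_a[i]).any() else -np.inf
            max_b = np.nanmax(mat_b[i]) if np.isfinite(mat_b[i]).any() else -np.inf
        if not (max_a > min_signal and max_b > min_signal):
            n_dropped += 1
            continue
        oa = _row_argmax(mat_a[i], offs)
        ob = _row_argmax(mat_b[i], offs)
        rows.append({"gene_id": g.gene_id, "antibody": antibody,
                     "offset_a": oa, "offset_b": ob, "shift": ob - oa})
    if not rows:
        raise ValueError(
            f"all {len(genes)} genes dropped (min_signal={min_signal})")
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_dropped
    return out


def test_shift_groups(shifts: pd.DataFrame, groups: pd.Series | dict,
                      baseline: float, min_group: int = 5,
                      alternative: str = "greater") -> pd.DataFrame:
    """Per-group one-sided Wilcoxon signed-rank of shift - baseline > 0.

    ``baseline`` is the mean shift of the all-expressed-genes set.  BH
    adjustment spans all group x antibody tests of the call; groups with
    fewer than ``min_group`` genes are reported NA.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    df = shifts.copy()
    df["group"] = groups.reindex(df["gene_id"]).values
    rows = []
    for (label, antibody), sub in df.groupby(["group", "antibody"],
                                             dropna=True):
        d = sub["shift"].values - baseline
        row = {"group": label, "antibody": antibody, "n": len(d),
               "median_shift": float(np.median(sub["shift"]))
               if len(d) else np.nan}
        if len(d) < min_group:
            row.update(statistic=np.nan, p=np.nan)
        else:
            res = stats.wilcoxon_signed_rank(d, alternative)
            row.update(statistic=res.statistic, p=res.p)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = stats.bh_adjust(out["p"].values)
    return out
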