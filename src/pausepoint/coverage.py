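"""Coverage tracks: loading, FP10M normalization, blacklists and NFRs.

A CoverageTrack holds one dense per-bp vector per chromosome.  Fragment
coverage is the count of fragments overlapping each base; FP10M rescales
by 1e7 / total aligned fragments so tracks from different library sizes
are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    data: dict = field(default_factory=dict)  # chrom -> float array
    units: str = "raw"                        # FP10M | RPM | raw | score
    strand: str = "unstranded"
    total_fragments: int | None = None

    def chroms(self):
        return sorted(self.data)

    def values(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            raise CoverageError(f"unknown chromosome {chrom!r}")
        return self.data[chrom]

    def scaled(self, factor: float, units: str) -> "CoverageTrack":
        return CoverageTrack({c: v * factor for c, v in self.data.items()},
                             units, self.strand, self.total_fragments)


def read_chrom_sizes(path) -> dict:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def read_bedgraph(path, chrom_sizes: dict) -> dict:
    """Dense per-bp arrays from a 4-column bedGraph; overlaps are an error."""
    data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom not in data:
                raise CoverageError(f"{path}:{lineno}: unknown chromosome {chrom}")
            s, e, v = int(start), int(end), float(value)
            if not (0 <= s < e <= chrom_sizes[chrom]):
                raise CoverageError(f"{path}:{lineno}: interval out of bounds")
            if covered[chrom][s:e].any():
                raise CoverageError(f"{path}:{lineno}: overlapping intervals")
            data[chrom][s:e] = v
            covered[chrom][s:e] = True
    return data


def write_bedgraph(track: CoverageTrack, path):
    """Run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            v = track.data[chrom]
            if len(v) == 0:
                continue
            change = np.nonzero(np.diff(v))[0] + 1
            bounds = np.concatenate([[0], change, [len(v)]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                val = v[s]
                if val != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{val:g}\n")


def read_fragments_bed(path, chrom_sizes: dict, min_frag: int | None = None,
                       max_frag: int | None = None):
    """Per-bp fragment-overlap counts from a BED3 of fragment intervals.

    Optional fragment-length filter (e.g. 70-250 bp for nucleosome data).
    Returns (data dict, n fragments kept).
    """
    diff = {c: np.zeros(n + 1) for c, n in chrom_sizes.items()}
    kept = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            if chrom not in diff:
                raise CoverageError(f"{path}:{lineno}: unknown chromosome {chrom}")
            s, e = int(start), int(end)
            if not (0 <= s < e <= chrom_sizes[chrom]):
                raise CoverageError(f"{path}:{lineno}: fragment out of bounds")
            frag_len = e - s
            if min_frag is not None and frag_len < min_frag:
                continue
            if max_frag is not None and frag_len > max_frag:
                continue
            diff[chrom][s] += 1
            diff[chrom][e] -= 1
            kept += 1
    data = {c: np.cumsum(d[:-1]) for c, d in diff.items()}
    return data, kept


def load_coverage(path, chrom_sizes: dict, normalize: str = "FP10M",
                  total_fragments: int | None = None,
                  min_frag: int | None = None,
                  max_frag: int | None = None) -> CoverageTrack:
    """Load a bedGraph (4 columns) or fragment BED (3 columns) as a track.

    For fragment input, coverage is the per-bp fragment-overlap count and
    the library size is the number of fragments kept; for bedGraph input
    the library size must be supplied when normalizing.
    """
    path = str(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    ncol = len(first.rstrip("\n").split("\t")) if first else 0
    if ncol >= 4:
        data = read_bedgraph(path, chrom_sizes)
        total = total_fragments
    elif ncol == 3:
        data, total = read_fragments_bed(path, chrom_sizes, min_frag, max_frag)
    elif ncol == 0:
        data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
        total = total_fragments if total_fragments is not None else 0
    else:
        raise CoverageError(f"{path}: cannot infer format ({ncol} columns)")

    track = CoverageTrack(data, "raw", "unstranded", total)
    if normalize in (None, "none"):
        return track
    if normalize not in ("FP10M", "RPM"):
        raise CoverageError(f"unknown normalization {normalize!r}")
    if not total:
        raise CoverageError(
            f"cannot apply {normalize} with zero/unknown library size")
    scale = (1e7 if normalize == "FP10M" else 1e6) / total
    out = track.scaled(scale, normalize)
    return out


def region_density(track: CoverageTrack, chrom: str, start: int,
                   end: int) -> float:
    """Mean signal per bp over [start, end)."""
    if end <= start:
        raise CoverageError("zero-length region")
    v = track.values(chrom)
    if start < 0 or end > len(v):
        raise CoverageError(
            f"region [{start},{end}) outside {chrom} (len {len(v)})")
    return float(v[start:end].sum() / (end - start))


# ---------------------------------------------------------------------------
# Blacklist (greylist-style, negative binomial threshold)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlacklistRegion:
    chrom: str
    start: int
    end: int
    n_supporting_controls: int


def _nb_threshold(sample: np.ndarray, quantile: float) -> float:
    m = sample.mean()
    v = sample.var(ddof=1)
    if v <= m or m == 0:
        return float(sps.poisson.ppf(quantile, max(m, 1e-12)))
    p = m / v
    r = m * m / (v - m)
    return float(sps.nbinom.ppf(quantile, r, p))


def build_blacklist(controls, bin_bp: int = 1000, n_random: int = 100,
                    sample_size: int = 30000, quantile: float = 0.95,
                    majority: float = 0.5, seed=None):
    """Flag bins with systematically high control signal.

    Per control track, the genome is cut into ``bin_bp`` bins and a
    negative binomial is fitted (method of moments; Poisson fallback when
    variance <= mean) to each of ``n_random`` random bin samples of size
    ``sample_size``; the track's threshold is the median of the fitted
    ``quantile`` quantiles.  Bins exceeding their track threshold in more
    than ``majority`` of the controls are blacklisted and adjacent flagged
    bins merged.  The random bin samples are drawn once and shared by all
    tracks, so the result is invariant to control ordering.
    """
    if len(controls) < 2:
        raise CoverageError("need at least 2 control tracks")
    chroms = controls[0].chroms()
    for t in controls[1:]:
        if t.chroms() != chroms:
            raise CoverageError("control tracks cover different chromosomes")

    bins = []  # (chrom, start, end)
    per_track_counts = []
    for t in controls:
        counts = []
        for chrom in chroms:
            v = t.values(chrom)
            n_bins = (len(v) + bin_bp - 1) // bin_bp
            if t is controls[0]:
                bins.extend((chrom, i * bin_bp, min((i + 1) * bin_bp, len(v)))
                            for i in range(n_bins))
            edge = np.arange(0, n_bins * bin_bp, bin_bp)
            sums = np.add.reduceat(v, edge)
            counts.append(np.rint(sums))
        per_track_counts.append(np.concatenate(counts))

    n_total = len(bins)
    if sample_size > n_total:
        warnings.warn(
            f"sample_size {sample_size} > {n_total} bins; sampling all bins")
        sample_size = n_total
    rng = np.random.default_rng(seed)
    sample_idx = [rng.choice(n_total, size=sample_size, replace=False)
                  for _ in range(n_random)]

    n_tracks = len(controls)
    support = np.zeros(n_total, dtype=int)
    for counts in per_track_counts:
        thresholds = [_nb_threshold(counts[idx], quantile)
                      for idx in sample_idx]
        thr = float(np.median(thresholds))
        support += counts > thr

    flagged = support > majority * n_tracks
    regions = []
    i = 0
    while i < n_total:
        if not flagged[i]:
            i += 1
            continue
        j = i
        chrom = bins[i][0]
        while (j + 1 < n_total and flagged[j + 1]
               and bins[j + 1][0] == chrom and bins[j + 1][1] == bins[j][2]):
            j += 1
        regions.append(BlacklistRegion(
            chrom, bins[i][1], bins[j][2],
            int(support[i:j + 1].min())))
        i = j + 1
    return regions


# ---------------------------------------------------------------------------
# Nucleosome-free regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NFRegion:
    chrom: str
    start: int
    end: int


def call_nfr(mnase: CoverageTrack, h3: CoverageTrack, min_len: int = 500,
             exclude=()):
    """Maximal runs where MNase and H3 are both below their genome-wide Q1.

    Runs must be strictly longer than ``min_len`` bp; runs overlapping any
    ``exclude`` region (peaks, blacklist) are removed.
    """
    if mnase.chroms() != h3.chroms():
        raise CoverageError("tracks cover different chromosomes")
    all_m = np.concatenate([mnase.values(c) for c in mnase.chroms()])
    all_h = np.concatenate([h3.values(c) for c in h3.chroms()])
    q1_m = float(np.percentile(all_m, 25))
    q1_h = float(np.percentile(all_h, 25))
    if q1_m == 0 or q1_h == 0:
        warnings.warn("first quartile is zero; no NFR can be called")
        return []
    excl = {}
    for reg in exclude:
        excl.setdefault(reg.chrom, []).append((reg.start, reg.end))
    out = []
    for chrom in mnase.chroms():
        mask = (mnase.values(chrom) < q1_m) & (h3.values(chrom) < q1_h)
        padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for s, e in zip(starts, ends):
            if e - s <= min_len:
                continue
            if any(s < xe and xs < e for xs, xe in excl.get(chrom, [])):
                continue
            out.append(NFRegion(chrom, int(s), int(e)))
    return out


def write_regions_bed(regions, path):
    with open(path, "w") as fh:
        for r in regions:
            score = getattr(r, "n_supporting_controls", 0)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{score}\n")
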