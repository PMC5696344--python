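"""Peak-set overlap, signal matrices, correlation, metaprofiles and
knockdown-dependency analysis.

These are the occupancy computations behind co-binding Venn counts, peak
heatmaps sorted by wild-type signal, Ash1/Mrg15 intensity correlation,
Mrg15-stratified H3K36me2 comparison, and retained-fraction analysis of
knockdown ChIP signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .coverage_quant import CoverageTrack, quantify_regions
from .genome_io import GenomicInterval, Peak, normalize_chrom

__all__ = [
    "OverlapResult",
    "PeakSignalMatrix",
    "ProfileMatrix",
    "StratifiedComparison",
    "overlap_peaks",
    "signal_matrix",
    "correlate_intensities",
    "metaprofile",
    "stratify_by_cofactor",
    "dependency_analysis",
    "call_peaks_simple",
]


# ---------------------------------------------------------------------------
# Peak-set overlap (Venn semantics: each peak counted once)
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    count_overlapping_a: int
    count_overlapping_b: int
    pairs: list[tuple[str, str]]

    @property
    def a_only(self) -> int:
        return self.n_a - self.count_overlapping_a

    @property
    def b_only(self) -> int:
        return self.n_b - self.count_overlapping_b

    @property
    def fraction_a(self) -> float:
        return self.count_overlapping_a / self.n_a if self.n_a else 0.0

    @property
    def fraction_b(self) -> float:
        return self.count_overlapping_b / self.n_b if self.n_b else 0.0


def overlap_peaks(set_a, set_b, min_overlap_bp: int = 1) -> OverlapResult:
    """Peak-wise overlap between two peak sets (half-open intervals).

    A peak in A is overlapping iff at least one peak in B shares
    >= ``min_overlap_bp`` bases with it.  Chromosome dialects are reconciled;
    fully disjoint chromosome namespaces raise instead of returning zero.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    chroms_a = {normalize_chrom(p.chrom) for p in set_a}
    chroms_b = {normalize_chrom(p.chrom) for p in set_b}
    if set_a and set_b and not (chroms_a & chroms_b):
        raise ValueError(
            "peak sets share no chromosomes — coordinate dialect mismatch? "
            f"(A: {sorted(chroms_a)[:5]}, B: {sorted(chroms_b)[:5]})"
        )
    trees: dict[str, IntervalTree] = {}
    for j, p in enumerate(set_b):
        trees.setdefault(normalize_chrom(p.chrom), IntervalTree()).addi(
            p.start, p.end, j
        )
    hit_a = np.zeros(len(set_a), dtype=bool)
    hit_b = np.zeros(len(set_b), dtype=bool)
    pairs = []
    for i, p in enumerate(set_a):
        tree = trees.get(normalize_chrom(p.chrom))
        if tree is None:
            continue
        for iv in tree.overlap(p.start, p.end):
            if min(p.end, iv.end) - max(p.start, iv.begin) >= min_overlap_bp:
                hit_a[i] = True
                hit_b[iv.data] = True
                pairs.append((_peak_name(p, i), _peak_name(set_b[iv.data], iv.data)))
    return OverlapResult(len(set_a), len(set_b), int(hit_a.sum()), int(hit_b.sum()),
                         sorted(pairs))


def _peak_name(p, i):
    return p.name if isinstance(p, Peak) else f"peak{i}"


# ---------------------------------------------------------------------------
# Signal matrices
# ---------------------------------------------------------------------------

@dataclass
class PeakSignalMatrix:
    """Rows: peaks; columns: (antibody, condition) samples; cells: densities."""

    peaks: list
    table: pd.DataFrame  # index: peak names, columns: "antibody:condition"

    def sorted_by(self, column: str, ascending: bool = False) -> "PeakSignalMatrix":
        order = self.table[column].sort_values(ascending=ascending, kind="stable").index
        tbl = self.table.loc[order]
        by_name = {(_peak_name(p, i)): p for i, p in enumerate(self.peaks)}
        return PeakSignalMatrix([by_name[n] for n in order], tbl)


def signal_matrix(peaks, samples: dict, fragment_size: int = 250,
                  depth_scale: float = 1e7) -> PeakSignalMatrix:
    """Quantify every peak in every sample.

    ``samples`` maps a sample key (e.g. ``"H3K36me2:WT"`` or an
    ``(antibody, condition)`` tuple) to a read DataFrame.  A peak lying on a
    chromosome absent from a sample raises (a silent 0 would be a lie).
    """
    regions = [p.interval if isinstance(p, Peak) else p for p in peaks]
    names = [_peak_name(p, i) for i, p in enumerate(peaks)]
    if len(set(names)) != len(names):
        raise ValueError("peak names must be unique for a signal matrix")
    cols = {}
    for key, reads in samples.items():
        label = key if isinstance(key, str) else ":".join(key)
        if len(reads) == 0:
            raise ValueError(f"sample {label!r} has an empty library")
        cols[label] = quantify_regions(reads, regions, fragment_size=fragment_size,
                                       depth_scale=depth_scale)
    table = pd.DataFrame(cols, index=pd.Index(names, name="peak"))
    return PeakSignalMatrix(list(peaks), table)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlate_intensities(x, y, transform="log2p1"):
    """Pearson correlation of two peak-intensity vectors.

    ``transform``: "log2p1" (log2(1+d), the default — intensity scatter axes
    are logarithmic), "none", or a callable.  Returns (R, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if transform == "log2p1":
        x, y = np.log2(1 + x), np.log2(1 + y)
    elif callable(transform):
        x, y = transform(x), transform(y)
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r), len(x)


# ---------------------------------------------------------------------------
# Metaprofiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Per-peak density rows over offset bins [-W, +W) around peak anchors."""

    offsets: np.ndarray  # bin start offsets relative to anchor
    matrix: np.ndarray   # (n_peaks, n_bins), NaN where off-chromosome
    peak_names: list[str]

    @property
    def mean_profile(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.peak_names, columns=self.offsets)


def metaprofile(peaks, track: CoverageTrack, window: int = 2000,
                bin_size: int | None = None, anchor: str = "midpoint") -> ProfileMatrix:
    """Average signal profile around peak anchors (default: midpoints).

    Rows truncated by a chromosome edge carry NaN in the missing columns and
    are excluded from those columns' means.
    """
    bin_size = bin_size or track.bin_size
    if window % bin_size:
        raise ValueError("window must be a multiple of bin size")
    if bin_size != track.bin_size:
        raise ValueError("profile bin size must equal the track bin size")
    n_bins = 2 * window // bin_size
    chrom_keys = {normalize_chrom(c): c for c in track.data}
    rows, names = [], []
    n_on = 0
    for i, p in enumerate(peaks):
        iv = p.interval if isinstance(p, Peak) else p
        key = chrom_keys.get(normalize_chrom(iv.chrom))
        row = np.full(n_bins, np.nan)
        if key is not None:
            n_on += 1
            v = track.data[key]
            if anchor == "midpoint":
                center = iv.midpoint
            elif anchor == "start":
                center = iv.start
            else:
                raise ValueError(f"unknown anchor {anchor!r}")
            b0 = (center - window) // bin_size
            idx = np.arange(b0, b0 + n_bins)
            ok = (idx >= 0) & (idx < len(v))
            row[ok] = v[idx[ok]]
        rows.append(row)
        names.append(_peak_name(p, i))
    if n_on == 0:
        raise ValueError("no peak lies on any chromosome of the track")
    offsets = np.arange(-window, window, bin_size)
    return ProfileMatrix(offsets, np.vstack(rows), names)


# ---------------------------------------------------------------------------
# Mrg15-stratified comparison
# ---------------------------------------------------------------------------

@dataclass
class StratifiedComparison:
    """H3K36me2 signal at Ash1 peaks split by cofactor (Mrg15) level.

    The peak set is partitioned into (cofactor group x primary-factor
    stratum) subgroups; pairs matched on the primary stratum differ only in
    the cofactor group.
    """

    labels: list[tuple[str, int]]  # (cofactor group, stratum index)
    groups: dict[tuple[str, int], np.ndarray]
    summary: pd.DataFrame  # median, q1, q3, n per subgroup

    def median(self, cofactor: str, stratum: int) -> float:
        return float(np.median(self.groups[(cofactor, stratum)]))


def stratify_by_cofactor(signal, cofactor_density, primary_density,
                         n_strata: int = 3) -> StratifiedComparison:
    """Split peaks by cofactor high/low (median), then by primary-factor
    abundance into quantile strata within each cofactor group; summarize
    ``signal`` per subgroup.

    With all cofactor densities equal the median split is degenerate and an
    error is raised rather than an arbitrary partition returned.
    """
    signal = np.asarray(signal, dtype=float)
    cof = np.asarray(cofactor_density, dtype=float)
    pri = np.asarray(primary_density, dtype=float)
    n = len(signal)
    if not (len(cof) == len(pri) == n):
        raise ValueError("signal/cofactor/primary vectors must align")
    if n < 2 * n_strata:
        raise ValueError(f"need >= {2 * n_strata} peaks for 2x{n_strata} subgroups")
    if np.ptp(cof) == 0:
        raise ValueError("cofactor median split degenerate: all densities equal")
    med = np.median(cof)
    high = cof > med
    if high.sum() == 0 or (~high).sum() == 0:
        # ties at the median: fall back to rank split
        order = np.argsort(cof, kind="stable")
        high = np.zeros(n, dtype=bool)
        high[order[n // 2:]] = True
    groups, labels, rows = {}, [], []
    for gname, mask in (("high", high), ("low", ~high)):
        sub_pri = pri[mask]
        if len(sub_pri) < n_strata:
            raise ValueError(f"cofactor group {gname!r} too small for {n_strata} strata")
        ranks = stats.rankdata(sub_pri, method="ordinal") - 1
        strata = np.floor(ranks * n_strata / len(sub_pri)).astype(int)
        sub_sig = signal[mask]
        for s in range(n_strata):
            vals = sub_sig[strata == s]
            groups[(gname, s)] = vals
            labels.append((gname, s))
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"cofactor": gname, "stratum": s, "n": len(vals),
                         "q1": q1, "median": q2, "q3": q3})
    return StratifiedComparison(labels, groups, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Knockdown dependency
# ---------------------------------------------------------------------------

def dependency_analysis(wt_density, kd_density, n_strata: int = 5,
                        epsilon: float | None = None) -> pd.DataFrame:
    """Retained signal fraction after knockdown, per wild-type-signal stratum.

    Peaks are binned into ``n_strata`` quantile strata of WT density
    (stratum 0 = weakest); the retained fraction per stratum is the median of
    kd / (wt + eps), eps defaulting to 0.01 x median(wt).  Returns a frame
    with columns (stratum, n, retained, wt_median) plus a ``monotone_up``
    attribute in ``.attrs``.
    """
    wt = np.asarray(wt_density, dtype=float)
    kd = np.asarray(kd_density, dtype=float)
    if wt.shape != kd.shape or wt.ndim != 1:
        raise ValueError("wt/kd density vectors must align")
    if len(wt) < n_strata:
        raise ValueError("fewer peaks than strata")
    med_wt = float(np.median(wt))
    if med_wt == 0 and wt.max() == 0:
        raise ValueError("all-zero wild-type densities")
    if epsilon is None:
        epsilon = 0.01 * med_wt if med_wt > 0 else 0.01 * wt[wt > 0].min()
    ratio = kd / (wt + epsilon)
    ranks = stats.rankdata(wt, method="ordinal") - 1
    strata = np.floor(ranks * n_strata / len(wt)).astype(int)
    rows = []
    for s in range(n_strata):
        mask = strata == s
        rows.append({
            "stratum": s,
            "n": int(mask.sum()),
            "retained": float(np.median(ratio[mask])),
            "wt_median": float(np.median(wt[mask])),
        })
    out = pd.DataFrame(rows)
    ret = out["retained"].to_numpy()
    out.attrs["monotone_up"] = bool(np.all(np.diff(ret) >= 0))
    out.attrs["epsilon"] = float(epsilon)
    return out


# ---------------------------------------------------------------------------
# Minimal fallback peak caller
# ---------------------------------------------------------------------------

def call_peaks_simple(track: CoverageTrack, threshold_sd: float = 4.0,
                      min_width: int = 200, merge_gap: int = 100) -> list[Peak]:
    """Threshold-based peak calling on a coverage track.

    This is deliberately minimal plumbing for inputs lacking an external peak
    caller: bins above background mean + ``threshold_sd`` x background sd are
    kept, nearby runs (<= merge_gap bp apart) merged, short runs
    (< min_width bp) dropped.  Background statistics are robust (median and
    MAD-derived sd) so peaks cannot inflate their own calling threshold.
    """
    all_bins = np.concatenate([v for v in track.data.values()]) if track.data else np.array([])
    if all_bins.size == 0 or np.ptp(all_bins) == 0:
        warnings.warn("flat coverage track: no peaks called")
        return []
    bg_mean = float(np.median(all_bins))
    bg_sd = 1.4826 * float(np.median(np.abs(all_bins - bg_mean)))
    if bg_sd == 0:  # half the bins identical; fall back to a trimmed std
        bg_sd = float(all_bins[all_bins <= np.percentile(all_bins, 99)].std())
    thr = bg_mean + threshold_sd * bg_sd
    peaks: list[Peak] = []
    k = 0
    bs = track.bin_size
    gap_bins = merge_gap // bs
    for chrom in sorted(track.data):
        v = track.data[chrom]
        above = v > thr
        if not above.any():
            continue
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > gap_bins + 1) + 1
        for run in np.split(idx, breaks):
            start, end = run[0] * bs, (run[-1] + 1) * bs
            end = min(end, track.chrom_sizes[chrom])
            if end - start < min_width:
                continue
            score = float(v[run[0]: run[-1] + 1].mean())
            k += 1
            peaks.append(Peak(GenomicInterval(chrom, start, end), f"peak_{k}", score))
    if not peaks:
        warnings.warn("no run exceeded the calling threshold")
    return peaks
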