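"""Single-cell copy-number profiling from low-pass binned read counts.

The input is a BED-like table of fixed genomic bins (chrom, start, end,
gc, count; 0-based half-open) — read alignment and counting are upstream.
The pipeline normalizes counts (library-size division, then a lowess GC
correction), detects changepoints per chromosome with penalized binary
segmentation on log2 ratios, rounds segment mean ratios to integer copy
numbers at an assumed ploidy, and computes coverage-uniformity quality
metrics (index of dispersion, Lorenz curve, Gini).  A qPCR pre-sequencing
library check (≥ 8/12 loci amplified at the expected Tm with Ct < 30) and
a driver-gene overlap annotation complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "QCRecord",
    "QCResult",
    "CNAProfile",
    "CoverageQuality",
    "qc_library",
    "normalize_bins",
    "segment_profile",
    "call_integer_cn",
    "profile_quality",
    "profile_concordance",
    "annotate_drivers",
    "call_cna_profile",
    "read_bins_tsv",
    "write_profile_tsv",
    "read_bed",
]

N_QC_LOCI = 12


@dataclass(frozen=True)
class QCRecord:
    """qPCR genome-integrity check of a single-cell amplification product
    at 12 fixed loci on different chromosomes."""

    library_id: str
    amplified_at_tm: tuple[bool, ...]
    ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.amplified_at_tm) != N_QC_LOCI or len(self.ct) != N_QC_LOCI:
            raise ValueError(f"QCRecord needs exactly {N_QC_LOCI} loci")
        if any(c <= 0 for c in self.ct):
            raise ValueError("Ct values must be positive")


@dataclass(frozen=True)
class QCResult:
    library_id: str
    passed: bool
    n_loci_pass: int
    locus_pass: tuple[bool, ...]
    reason: str


def qc_library(record: QCRecord, max_ct: float = 30.0,
               min_loci: int = 8) -> QCResult:
    """Library pass/fail: a locus passes iff amplified at the expected Tm
    AND Ct strictly below ``max_ct``; the library passes with at least
    ``min_loci`` passing loci."""
    locus_pass = tuple(
        bool(a) and (c < max_ct)
        for a, c in zip(record.amplified_at_tm, record.ct)
    )
    n = sum(locus_pass)
    passed = n >= min_loci
    reason = (
        f"{n}/{N_QC_LOCI} loci amplified at expected Tm with Ct < {max_ct:g} "
        f"({'>=' if passed else '<'} {min_loci} required)"
    )
    return QCResult(record.library_id, passed, n, locus_pass, reason)


def _check_bins(bins: pd.DataFrame) -> None:
    required = {"chrom", "start", "end", "count"}
    if not required.issubset(bins.columns):
        raise ValueError(f"bins need columns {sorted(required)}")
    for chrom, sub in bins.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (np.diff(starts) <= 0).any() or (starts[1:] < ends[:-1]).any():
            raise ValueError(f"bins not sorted/non-overlapping on {chrom}")


def normalize_bins(
    bins: pd.DataFrame,
    method: str = "lowess",
    lowess_frac: float = 0.3,
    min_bins: int = 100,
) -> np.ndarray:
    """Library-size and GC-normalized per-bin ratios (mean 1).

    Counts are divided by their mean, then by a fitted GC response
    (lowess by default, or a quadratic fit), and renormalized to mean 1.
    Zero-count bins are retained.
    """
    _check_bins(bins)
    if len(bins) < min_bins:
        raise ValueError(f"need at least {min_bins} bins")
    counts = bins["count"].to_numpy(dtype=float)
    if counts.sum() <= 0:
        raise ValueError("all-zero counts")
    ratio = counts / counts.mean()
    gc = bins["gc"].to_numpy(dtype=float)
    if method == "lowess":
        fitted = lowess(ratio, gc, frac=lowess_frac, return_sorted=False)
    elif method == "quadratic":
        coeffs = np.polyfit(gc, ratio, 2)
        fitted = np.polyval(coeffs, gc)
    else:
        raise ValueError(f"unknown GC-correction method {method!r}")
    fitted = np.clip(fitted, 0.05, None)
    corrected = ratio / fitted
    return corrected / corrected.mean()


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single changepoint of a 1-D series under squared-error cost.

    Returns (split index, cost reduction); split at i puts ``x[:i]`` left.
    """
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    total = cs2[n] - cs[n] ** 2 / n
    i = np.arange(1, n)
    left = cs2[i] - cs[i] ** 2 / i
    right = (cs2[n] - cs2[i]) - (cs[n] - cs[i]) ** 2 / (n - i)
    gains = total - (left + right)
    j = int(np.argmax(gains))
    return j + 1, float(gains[j])


def _constrained_split(seg: np.ndarray, min_size: int) -> tuple[int, float]:
    """Best single split with both parts at least ``min_size`` long."""
    n = len(seg)
    cs = np.concatenate([[0.0], np.cumsum(seg)])
    cs2 = np.concatenate([[0.0], np.cumsum(seg * seg)])
    total = cs2[n] - cs[n] ** 2 / n
    i = np.arange(min_size, n - min_size + 1)
    left = cs2[i] - cs[i] ** 2 / i
    right = (cs2[n] - cs2[i]) - (cs[n] - cs[i]) ** 2 / (n - i)
    gains = total - (left + right)
    j = int(np.argmax(gains))
    return int(i[j]), float(gains[j])


def _best_interior(seg: np.ndarray, min_size: int,
                   max_pairs_n: int = 2000) -> tuple[int, int, float]:
    """Best interior carve-out [i, j): the two flanks share one mean (the
    circular variant of the split test), so a short plateau in the middle
    of a long segment is found directly."""
    n = len(seg)
    if n > max_pairs_n:
        return 0, 0, -np.inf
    cs = np.concatenate([[0.0], np.cumsum(seg)])
    cs2 = np.concatenate([[0.0], np.cumsum(seg * seg)])
    total = cs2[n] - cs[n] ** 2 / n
    i = np.arange(min_size, n - 2 * min_size + 1)
    j = np.arange(2 * min_size, n - min_size + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    valid = (jj - ii) >= min_size
    s_mid = cs[jj] - cs[ii]
    q_mid = cs2[jj] - cs2[ii]
    n_mid = np.maximum(jj - ii, 1)
    sse_mid = q_mid - s_mid**2 / n_mid
    s_out = cs[n] - s_mid
    n_out = np.maximum(n - n_mid, 1)
    sse_out = (cs2[n] - q_mid) - s_out**2 / n_out
    gains = np.where(valid, total - sse_mid - sse_out, -np.inf)
    flat = int(np.argmax(gains))
    bi, bj = np.unravel_index(flat, gains.shape)
    return int(ii[bi, bj]), int(jj[bi, bj]), float(gains[bi, bj])


def _binary_segment(x: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Recursive penalized segmentation; returns sorted interior breakpoints.

    Each recursion considers the best single split (one changepoint, one
    penalty) and the best interior carve-out (two changepoints, two
    penalties) and applies whichever clears its penalty by more.
    """
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2 * min_size:
            return
        seg = x[lo:hi]
        split, gain1 = _constrained_split(seg, min_size)
        score1 = gain1 - penalty
        score2 = -np.inf
        if hi - lo >= 3 * min_size:
            i, j, gain2 = _best_interior(seg, min_size)
            score2 = gain2 - 2.0 * penalty
        if max(score1, score2) <= 0:
            return
        if score1 >= score2:
            cuts = [lo + split]
        else:
            cuts = [lo + i, lo + j]
        breaks.extend(cuts)
        edges = [lo] + cuts + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(breaks)


def segment_profile(
    ratios: np.ndarray,
    chroms: Sequence[str],
    penalty: float | None = None,
    penalty_mult: float = 3.0,
    min_size: int = 3,
    log_floor: float = -4.0,
) -> list[tuple[int, int]]:
    """Per-chromosome changepoint detection on log2 ratios.

    Binary segmentation with a penalized squared-error cost: a split is
    accepted when its cost reduction exceeds ``penalty`` (default
    ``penalty_mult · σ² · log n`` per chromosome, with σ estimated from
    median absolute first differences).  The default multiplier sits just
    above the expected maximal spurious gain on a constant profile
    (≈ 2σ² log n) because the first cut through a short interior plateau
    captures only part of its step and must not be rejected.  Segments
    never cross chromosome boundaries.  Returns half-open global
    bin-index ranges.
    """
    ratios = np.asarray(ratios, dtype=float)
    chroms = np.asarray(chroms)
    if len(ratios) != len(chroms):
        raise ValueError("ratios and chroms must align")
    log2r = np.log2(np.clip(ratios, 2.0**log_floor, None))
    segments: list[tuple[int, int]] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        n = hi - lo
        if n < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 bins")
        x = log2r[lo:hi]
        if penalty is None:
            diffs = np.diff(x)
            sigma = np.median(np.abs(diffs)) / (np.sqrt(2.0) * 0.6745) \
                if len(diffs) else 0.0
            sigma = max(sigma, 1e-3)
            pen = penalty_mult * sigma**2 * np.log(n)
        else:
            pen = penalty
        breaks = _binary_segment(x, pen, min_size)
        edges = [lo] + [lo + b for b in breaks] + [hi]
        segments.extend((edges[i], edges[i + 1]) for i in range(len(edges) - 1))
    return segments


def call_integer_cn(
    ratios: np.ndarray,
    segments: Sequence[tuple[int, int]],
    ploidy: int = 2,
    optimize_ploidy: bool = False,
) -> np.ndarray:
    """Integer CN per segment: round(ploidy × segment mean ratio), ≥ 0.

    With ``optimize_ploidy`` a scaling-factor grid (1.5–4.0) minimizing
    the distance of scaled segment means to integers replaces the fixed
    ploidy scale; off by default for determinism.
    """
    ratios = np.asarray(ratios, dtype=float)
    means = np.array([ratios[a:b].mean() for a, b in segments])
    scale = float(ploidy)
    if optimize_ploidy:
        weights = np.array([b - a for a, b in segments], dtype=float)
        grid = np.arange(1.5, 4.0001, 0.05)
        errs = [
            np.average(np.abs(s * means - np.round(s * means)), weights=weights)
            for s in grid
        ]
        scale = float(grid[int(np.argmin(errs))])
    cn = np.floor(scale * means + 0.5).astype(int)  # round half up
    return np.maximum(cn, 0)


@dataclass(frozen=True)
class CoverageQuality:
    """Coverage-uniformity metrics of raw bin counts."""

    index_of_dispersion: float
    lorenz_x: np.ndarray
    lorenz_y: np.ndarray
    gini: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray


def profile_quality(counts: Sequence[float], n_hist_bins: int = 50) -> CoverageQuality:
    """Index of dispersion (sample variance / mean), Lorenz curve, Gini
    coefficient and a read-count histogram."""
    arr = np.asarray(counts, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 bins")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("quality metrics undefined for zero mean coverage")
    dispersion = float(arr.var(ddof=1) / mean)
    s = np.sort(arr)
    cum = np.concatenate([[0.0], np.cumsum(s)])
    lorenz_y = cum / cum[-1]
    lorenz_x = np.linspace(0.0, 1.0, arr.size + 1)
    gini = float(1.0 - 2.0 * np.trapezoid(lorenz_y, lorenz_x))
    hist, edges = np.histogram(arr, bins=n_hist_bins)
    return CoverageQuality(dispersion, lorenz_x, lorenz_y, gini, hist, edges)


@dataclass
class CNAProfile:
    """Ordered genomic bins with normalized ratios, segments and integer CN."""

    bins: pd.DataFrame              # chrom, start, end, gc, count
    ratios: np.ndarray              # per-bin normalized ratio
    segments: pd.DataFrame          # chrom, start, end, start_bin, end_bin,
                                    # mean_ratio, cn
    ploidy: int = 2

    def __post_init__(self) -> None:
        if (self.segments["cn"] < 0).any():
            raise ValueError("integer CN must be >= 0")
        # segments must partition the bin sequence
        edges = self.segments[["start_bin", "end_bin"]].to_numpy()
        if len(edges):
            if edges[0, 0] != 0 or edges[-1, 1] != len(self.bins):
                raise ValueError("segments do not span all bins")
            if (edges[1:, 0] != edges[:-1, 1]).any():
                raise ValueError("segments do not partition the bin sequence")

    @property
    def bin_cn(self) -> np.ndarray:
        """Per-bin integer CN."""
        out = np.empty(len(self.bins), dtype=int)
        for _, seg in self.segments.iterrows():
            out[int(seg["start_bin"]):int(seg["end_bin"])] = int(seg["cn"])
        return out

    def quality(self) -> CoverageQuality:
        return profile_quality(self.bins["count"].to_numpy(dtype=float))


def call_cna_profile(
    bins: pd.DataFrame,
    ploidy: int = 2,
    gc_method: str = "lowess",
    optimize_ploidy: bool = False,
    **segment_kwargs,
) -> CNAProfile:
    """Full pipeline: normalize → segment → integer CN calls."""
    ratios = normalize_bins(bins, method=gc_method)
    chroms = bins["chrom"].to_numpy()
    seg_ranges = segment_profile(ratios, chroms, **segment_kwargs)
    cn = call_integer_cn(ratios, seg_ranges, ploidy=ploidy,
                         optimize_ploidy=optimize_ploidy)
    seg_rows = []
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for (a, b), c in zip(seg_ranges, cn):
        seg_rows.append({
            "chrom": bins["chrom"].iloc[a],
            "start": int(starts[a]),
            "end": int(ends[b - 1]),
            "start_bin": a,
            "end_bin": b,
            "mean_ratio": float(ratios[a:b].mean()),
            "cn": int(c),
        })
    segments = pd.DataFrame(seg_rows)
    return CNAProfile(bins=bins.reset_index(drop=True), ratios=ratios,
                      segments=segments, ploidy=ploidy)


def profile_concordance(
    a: CNAProfile, b: CNAProfile, on: str = "cn"
) -> float:
    """Pearson r between two profiles over their shared bin grid.

    ``on="cn"`` compares per-bin integer CN (default); ``on="ratio"``
    compares normalized ratios.
    """
    if len(a.bins) != len(b.bins):
        raise ValueError("profiles are on different bin grids")
    for col in ("chrom", "start", "end"):
        if not (a.bins[col].to_numpy() == b.bins[col].to_numpy()).all():
            raise ValueError("profiles are on different bin grids")
    if on == "cn":
        x, y = a.bin_cn.astype(float), b.bin_cn.astype(float)
    elif on == "ratio":
        x, y = a.ratios, b.ratios
    else:
        raise ValueError(f"unknown comparison basis {on!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("concordance undefined for a constant profile")
    return float(stats.pearsonr(x, y).statistic)


def annotate_drivers(profile: CNAProfile, genes: pd.DataFrame) -> pd.DataFrame:
    """Overlap a gene table with gained/lost segments.

    Each gene overlapping at least one non-neutral (CN ≠ ploidy) segment
    is reported with the segment of maximal overlap (ties go to the higher
    CN), its direction (``gained``/``lost``/``neutral`` from the assigned
    segment), and a flag when the gene spans a segment boundary.
    """
    if genes.empty:
        return pd.DataFrame(
            columns=["gene", "chrom", "start", "end", "cn", "direction",
                     "boundary_spanning"]
        )
    required = {"chrom", "start", "end", "name"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("malformed gene intervals (end <= start)")
    seg = profile.segments
    rows = []
    for _, gene in genes.iterrows():
        hits = seg[
            (seg["chrom"] == gene["chrom"])
            & (seg["start"] < gene["end"])
            & (seg["end"] > gene["start"])
        ]
        if hits.empty:
            continue
        overlaps = np.minimum(hits["end"], gene["end"]) - np.maximum(
            hits["start"], gene["start"]
        )
        order = hits.assign(_ov=overlaps.to_numpy()).sort_values(
            ["_ov", "cn"], ascending=[False, False]
        )
        best = order.iloc[0]
        if (hits["cn"] != profile.ploidy).sum() == 0:
            continue  # only neutral overlap: not a CNA hit
        cn = int(best["cn"])
        direction = ("gained" if cn > profile.ploidy
                     else "lost" if cn < profile.ploidy else "neutral")
        rows.append({
            "gene": gene["name"],
            "chrom": gene["chrom"],
            "start": int(gene["start"]),
            "end": int(gene["end"]),
            "cn": cn,
            "direction": direction,
            "boundary_spanning": bool(len(hits) > 1),
        })
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "cn", "direction",
                       "boundary_spanning"]
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def read_bins_tsv(path: str | Path) -> pd.DataFrame:
    """Read a BED-like bin-count table (chrom, start, end, gc, count);
    header optional."""
    first = Path(path).open().readline()
    has_header = first.lower().startswith("chrom")
    bins = pd.read_csv(
        path, sep="\t",
        header=0 if has_header else None,
        names=None if has_header else ["chrom", "start", "end", "gc", "count"],
    )
    _check_bins(bins)
    return bins


def write_profile_tsv(profile: CNAProfile, path: str | Path) -> None:
    """Write per-bin ratios and CN as TSV plus a segment-level JSON."""
    path = Path(path)
    out = profile.bins.copy()
    out["ratio"] = profile.ratios
    out["cn"] = profile.bin_cn
    out.to_csv(path, sep="\t", index=False)
    seg_path = path.with_suffix(".segments.json")
    seg_path.write_text(profile.segments.to_json(orient="records", indent=2))


def read_bed(path: str | Path, name_col: bool = True) -> pd.DataFrame:
    """Read a BED file of gene intervals (chrom, start, end[, name])."""
    names = ["chrom", "start", "end"] + (["name"] if name_col else [])
    try:
        genes = pd.read_csv(path, sep="\t", header=None, comment="#",
                            usecols=range(len(names)), names=names)
    except Exception as exc:
        raise ValueError(f"malformed BED file: {exc}") from exc
    if genes[["start", "end"]].isna().any().any():
        raise ValueError("malformed BED file: missing coordinates")
    if not name_col:
        genes["name"] = [f"feature_{i}" for i in range(len(genes))]
    return genes
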