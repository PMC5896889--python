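"""Bulked segregant analysis: marker pools and the sliding-window scan.

Round 1 is qualitative: replicate pools of green and white seedlings are
genotyped at size-polymorphic markers, and a marker is called associated
when every white pool is fixed (or nearly fixed) for one parental allele
while green pools remain mixed.

Round 2 is the genome-wide scan: per-SNP alternate-allele frequencies are
computed for a white and a green pool, averaged in 200-SNP sliding windows
with 100-SNP overlap, and windows in the top divergence quantile (by the
absolute value of the signed mean difference) are merged into candidate
regions. The least divergent windows (smallest mean absolute difference)
flag regions fixed identically in both pools — the signature of a locus
whose genotype the pooling design held constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig",
    "per_snp_freq",
    "window_scan",
    "call_regions",
    "RegionCalls",
    "marker_bsa",
]


@dataclass
class ScanConfig:
    """Tuning knobs of the window scan.

    Windows are defined in SNP-index space. ``top_quantile`` selects the
    most divergent windows (default top 5%), ``bottom_quantile`` the least
    divergent (default bottom 0.5%); candidate regions need at least
    ``min_contiguous`` consecutive flagged windows. SNPs below ``min_depth``
    reads in either pool are masked out before windowing.
    """

    window: int = 200
    step: int = 100
    top_quantile: float = 0.05
    bottom_quantile: float = 0.005
    min_depth: int = 4
    min_contiguous: int = 3

    def __post_init__(self):
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")
        for q in (self.top_quantile, self.bottom_quantile):
            if not (0.0 < q < 0.5):
                raise ValueError("quantiles must lie in (0, 0.5)")


def per_snp_freq(counts: pd.DataFrame, min_depth: int = 4) -> pd.DataFrame:
    """Alternate-allele frequency per SNP from a pool-count table.

    Expects columns chrom, pos, ref_depth, alt_depth sorted by (chrom, pos).
    Adds ``depth``, ``freq`` and a boolean ``masked`` column; SNPs with
    depth below ``min_depth`` are masked (freq NaN), not dropped, so the
    table keeps one row per panel SNP.
    """
    df = counts.copy()
    df["depth"] = df["ref_depth"] + df["alt_depth"]
    masked = df["depth"] < min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = df["alt_depth"] / df["depth"]
    df["freq"] = np.where(masked, np.nan, freq)
    df["masked"] = masked
    return df


def _merge_pools(freq_a: pd.DataFrame, freq_b: pd.DataFrame) -> pd.DataFrame:
    merged = freq_a.merge(
        freq_b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner"
    )
    usable = ~(merged["masked_a"] | merged["masked_b"])
    merged = merged.loc[usable].sort_values(["chrom", "pos"], kind="mergesort")
    return merged.reset_index(drop=True)


def window_scan(freq_a: pd.DataFrame, freq_b: pd.DataFrame,
                config: ScanConfig | None = None) -> pd.DataFrame:
    """Sliding-window mean allele-frequency differences between two pools.

    Inputs are :func:`per_snp_freq` tables for pool A (white) and pool B
    (green). Only SNPs unmasked in both pools enter windows; windows advance
    by ``config.step`` SNPs and trailing windows shorter than
    ``config.window`` are dropped. Returns one row per window with the
    signed mean difference (A - B) and the mean absolute difference.
    """
    if config is None:
        config = ScanConfig()
    merged = _merge_pools(freq_a, freq_b)
    rows = []
    for chrom, sub in merged.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        diff = (sub["freq_a"] - sub["freq_b"]).to_numpy()
        s = len(sub)
        if s < config.window:
            continue
        n_windows = (s - config.window) // config.step + 1
        for w in range(n_windows):
            lo = w * config.step
            hi = lo + config.window
            d = diff[lo:hi]
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(pos[lo]),
                    "end_bp": int(pos[hi - 1]) + 1,
                    "n_snps": config.window,
                    "mean_diff": float(d.mean()),
                    "mean_absdiff": float(np.abs(d).mean()),
                    "window_index": w,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "n_snps",
            "mean_diff", "mean_absdiff", "window_index",
        ],
    )


@dataclass
class RegionCalls:
    """Candidate intervals from the scan, with their peak windows.

    ``top``/``bottom`` are merged contiguous regions; ``top_windows`` and
    ``bottom_windows`` keep the individual flagged windows (the dots one
    would plot along the genome), which matter when a scan has few windows
    and a real signal spans fewer than ``min_contiguous`` of them.
    """

    top: pd.DataFrame
    bottom: pd.DataFrame
    top_threshold: float
    bottom_threshold: float
    top_windows: pd.DataFrame = None
    bottom_windows: pd.DataFrame = None


def _merge_flagged(stats: pd.DataFrame, flagged: np.ndarray,
                   min_contiguous: int, peak_col: str,
                   peak_best=np.argmax) -> pd.DataFrame:
    regions = []
    for chrom, sub in stats.groupby("chrom", sort=False):
        f = flagged[sub.index.to_numpy()]
        widx = sub["window_index"].to_numpy()
        run = []
        for i in range(len(sub)):
            if f[i] and (not run or widx[i] == widx[run[-1]] + 1):
                run.append(i)
            else:
                if len(run) >= min_contiguous:
                    regions.append((chrom, sub, run))
                run = [i] if f[i] else []
        if len(run) >= min_contiguous:
            regions.append((chrom, sub, run))
    rows = []
    for chrom, sub, run in regions:
        block = sub.iloc[run]
        vals = block[peak_col].to_numpy()
        peak = block.iloc[int(peak_best(vals))]
        rows.append(
            {
                "chrom": chrom,
                "start_bp": int(block["start_bp"].min()),
                "end_bp": int(block["end_bp"].max()),
                "n_windows": len(run),
                "peak_start_bp": int(peak["start_bp"]),
                "peak_end_bp": int(peak["end_bp"]),
                "peak_stat": float(peak[peak_col]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "n_windows",
            "peak_start_bp", "peak_end_bp", "peak_stat",
        ],
    )


def call_regions(stats: pd.DataFrame,
                 config: ScanConfig | None = None) -> RegionCalls:
    """Quantile-threshold the window statistics and merge runs into regions.

    Top list: windows whose |signed mean difference| reaches the
    ``1 - top_quantile`` quantile. Bottom list: windows whose mean absolute
    difference falls at or below the ``bottom_quantile`` quantile. Runs of
    at least ``min_contiguous`` consecutive windows become half-open bp
    intervals, each reported with its peak window.
    """
    if config is None:
        config = ScanConfig()
    if stats.empty:
        raise ValueError("no windows to call regions from")
    stats = stats.reset_index(drop=True)
    absdiff = stats["mean_diff"].abs().to_numpy()
    top_thr = float(np.quantile(absdiff, 1.0 - config.top_quantile))
    bot_thr = float(np.quantile(stats["mean_absdiff"], config.bottom_quantile))

    stats = stats.assign(abs_mean_diff=absdiff)
    top_flag = absdiff >= top_thr
    bottom_flag = stats["mean_absdiff"].to_numpy() <= bot_thr
    top = _merge_flagged(
        stats, top_flag, config.min_contiguous, "abs_mean_diff", np.argmax
    )
    bottom = _merge_flagged(
        stats, bottom_flag, config.min_contiguous, "mean_absdiff", np.argmin
    )
    return RegionCalls(top, bottom, top_thr, bot_thr,
                       stats.loc[top_flag].reset_index(drop=True),
                       stats.loc[bottom_flag].reset_index(drop=True))


def marker_bsa(calls: pd.DataFrame, tolerance: int = 1,
               max_missing_fraction: float = 0.5) -> pd.DataFrame:
    """Replicate-pool marker screen (round-1 BSA).

    ``calls`` has one row per (marker, pool) with columns marker, pool,
    phenotype ('white'|'green') and call ('G-only'|'N-only'|'mixed'|'missing').
    A marker is associated when all white pools — allowing up to
    ``tolerance`` exceptions, the "only (or mostly)" rule — are fixed for
    the same parental allele while at least one green pool is mixed.
    Markers missing in more than half the pools are excluded (flag column).
    """
    required = {"marker", "pool", "phenotype", "call"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    n_pools = calls["pool"].nunique()
    wp = calls["phenotype"].eq("white")
    if calls.loc[wp, "pool"].nunique() < 2 or calls.loc[~wp, "pool"].nunique() < 2:
        raise ValueError("need >= 2 replicate pools per phenotype")
    rows = []
    for marker, sub in calls.groupby("marker", sort=False):
        present = sub[sub["call"] != "missing"]
        if len(present) < n_pools / 2:
            rows.append({"marker": marker, "associated": False,
                         "fixed_allele": None, "excluded": True})
            continue
        white = present[present["phenotype"] == "white"]["call"]
        green = present[present["phenotype"] == "green"]["call"]
        associated = False
        fixed = None
        for allele_call, allele in (("G-only", "G"), ("N-only", "N")):
            n_off = (white != allele_call).sum()
            if len(white) > 0 and n_off <= tolerance and (green == "mixed").any():
                associated = True
                fixed = allele
                break
        rows.append({"marker": marker, "associated": associated,
                     "fixed_allele": fixed, "excluded": False})
    return pd.DataFrame(rows)
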