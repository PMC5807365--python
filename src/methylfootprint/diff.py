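"""Paired per-tile and per-CGI differential methylation testing.

For each 200 bp tile, CpG dyads covered by >= 10 reads in BOTH samples
are paired positionally; tiles with fewer than 3 shared CpGs are
excluded.  The per-tile statistic is the paired t test on the per-CpG
level differences, p values are Benjamini-Hochberg adjusted over the
genome-wide family of tested tiles, and a tile is significant iff
adjusted p < 0.05 AND |delta| > 0.10.  Per-CGI tests are identical
except the interval set replaces the tile grid and the delta cutoff is
waived.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import GenomicInterval
from .tiles import tile_of

__all__ = [
    "bh_adjust",
    "paired_stats",
    "tile_diff",
    "cgi_diff",
    "call_significant",
]

STATS_COLUMNS = [
    "chrom", "start", "end", "n_shared_cpgs",
    "mean_a", "mean_b", "delta", "t", "p_raw", "p_adj", "significant",
]


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    adj_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj


def paired_stats(d: np.ndarray) -> tuple[float, float]:
    """Paired t statistic and two-sided p for one vector of differences.

    t = mean(d) * sqrt(n) / sd(d) with n-1 df.  Degenerate sd = 0:
    all-zero differences give p = 1 (t = 0); nonzero mean with zero sd
    gives p = 0 with t = signed infinity.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    m = d.mean()
    sd = d.std(ddof=1) if n > 1 else 0.0
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 1.0
        return float(np.sign(m) * np.inf), 0.0
    t = m * np.sqrt(n) / sd
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def call_significant(
    p_adj: np.ndarray, delta: np.ndarray, config: AnalysisConfig, use_delta: bool = True
) -> np.ndarray:
    """The dual significance rule: p_adj < alpha and |delta| > min_delta.

    ``use_delta=False`` applies the p-value criterion alone (per-CGI
    rule).  With ``gain_only`` set, only positive deltas qualify.
    """
    eff_delta = delta if config.gain_only else np.abs(delta)
    sig = p_adj < config.alpha
    if use_delta:
        sig = sig & (eff_delta > config.min_delta)
    elif config.gain_only:
        sig = sig & (eff_delta > 0)
    return sig


def _grouped_tests(
    merged: pd.DataFrame,
    group_cols: list[str],
    config: AnalysisConfig,
    use_delta: bool,
) -> pd.DataFrame:
    """Vectorized paired tests over groups of shared, covered dyads."""
    merged = merged.assign(d=merged["level_b"] - merged["level_a"])
    g = merged.groupby(group_cols, as_index=False)
    agg = g.agg(
        n_shared_cpgs=("d", "size"),
        mean_a=("level_a", "mean"),
        mean_b=("level_b", "mean"),
        d_mean=("d", "mean"),
        d_var=("d", "var"),  # ddof=1; NaN for n=1
    )
    agg = agg[agg["n_shared_cpgs"] >= config.min_cpgs].reset_index(drop=True)
    n = agg["n_shared_cpgs"].to_numpy(dtype=float)
    d_mean = agg["d_mean"].to_numpy()
    sd = np.sqrt(agg["d_var"].to_numpy())
    t = np.full(len(agg), np.nan)
    p = np.full(len(agg), np.nan)
    degen = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = ~degen
        t[ok] = d_mean[ok] * np.sqrt(n[ok]) / sd[ok]
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n[ok] - 1)
    t[degen & (d_mean == 0)] = 0.0
    p[degen & (d_mean == 0)] = 1.0
    nz = degen & (d_mean != 0)
    t[nz] = np.sign(d_mean[nz]) * np.inf
    p[nz] = 0.0
    agg["delta"] = agg["mean_b"] - agg["mean_a"]
    agg["t"] = t
    agg["p_raw"] = p
    agg["p_adj"] = bh_adjust(p) if len(agg) else np.array([])
    agg["significant"] = call_significant(
        agg["p_adj"].to_numpy(), agg["delta"].to_numpy(), config, use_delta=use_delta
    )
    return agg.drop(columns=["d_mean", "d_var"])


def _pair(calls_a: pd.DataFrame, calls_b: pd.DataFrame, min_cov: int) -> pd.DataFrame:
    a = calls_a[calls_a["n_total"] >= min_cov]
    b = calls_b[calls_b["n_total"] >= min_cov]
    return pd.merge(
        a[["chrom", "pos", "level"]],
        b[["chrom", "pos", "level"]],
        on=["chrom", "pos"],
        suffixes=("_a", "_b"),
    )


def tile_diff(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    config: AnalysisConfig | None = None,
    width: int | None = None,
) -> pd.DataFrame:
    """Genome-wide per-tile paired tests between two samples.

    Returns one row per tested tile (>= ``min_cpgs`` shared dyads with
    >= ``min_cov_test`` reads in both samples) with columns
    ``chrom, start, end, n_shared_cpgs, mean_a, mean_b, delta, t, p_raw,
    p_adj, significant``.  The BH family is all tested tiles genome-wide.
    """
    config = config or AnalysisConfig()
    width = width or config.tile_width
    merged = _pair(calls_a, calls_b, config.min_cov_test)
    if len(merged) == 0:
        return pd.DataFrame(columns=STATS_COLUMNS)
    merged["start"] = tile_of(merged["pos"].to_numpy(), width) * width
    out = _grouped_tests(merged, ["chrom", "start"], config, use_delta=True)
    if len(out) == 0:
        return pd.DataFrame(columns=STATS_COLUMNS)
    out["end"] = out["start"] + width
    return out[STATS_COLUMNS].sort_values(["chrom", "start"]).reset_index(drop=True)


def cgi_diff(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    cgi_intervals: Sequence[GenomicInterval],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-CGI paired tests; significance by adjusted p alone (no delta
    cutoff), per the island-level rule."""
    config = config or AnalysisConfig()
    merged = _pair(calls_a, calls_b, config.min_cov_test)
    if len(merged) == 0:
        return pd.DataFrame(columns=STATS_COLUMNS + ["name"])
    frames = []
    for iv in cgi_intervals:
        sel = merged[
            (merged["chrom"] == iv.chrom)
            & (merged["pos"] >= iv.start)
            & (merged["pos"] < iv.end)
        ]
        if len(sel) == 0:
            continue
        frames.append(
            sel.assign(start=iv.start, end=iv.end, name=iv.name or f"{iv.chrom}:{iv.start}")
        )
    if not frames:
        return pd.DataFrame(columns=STATS_COLUMNS + ["name"])
    stacked = pd.concat(frames, ignore_index=True)
    out = _grouped_tests(stacked, ["chrom", "start", "end", "name"], config, use_delta=False)
    if len(out) == 0:
        return pd.DataFrame(columns=STATS_COLUMNS + ["name"])
    return out[STATS_COLUMNS + ["name"]].sort_values(["chrom", "start"]).reset_index(drop=True)
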