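"""On-target vs off-target quantification of dCas9-methyltransferase
activity, time-course gain curves, and the CGI/H3K4me3 summaries.

The on-target window is the 200 bp immediately downstream (3' of the
protospacer on its strand) of each sgRNA.  Its matched off-target
background is the set of grid 200 bp tiles whose wild-type methylation
lies within +/- 0.05 of the on-target wild-type level — tiles with the
same potential to become methylated.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import GenomicInterval, SgRNATarget
from .tiles import tile_mean, tile_means, tile_of

logger = logging.getLogger(__name__)

__all__ = [
    "on_target_tile",
    "matched_background",
    "on_off_contrast",
    "gain_curve",
    "top_k_overlap",
    "cgi_class_summary",
    "cgi_k4_score",
    "delta_histogram",
    "context_summary",
]

#: a time course is a mapping day -> call table; clones are mappings
#: clone -> time course
TimeCourse = Mapping[int, pd.DataFrame]


def on_target_tile(
    sgrna: SgRNATarget,
    config: AnalysisConfig | None = None,
    chrom_size: int | None = None,
    downstream: str = "3prime",
) -> GenomicInterval:
    """The on-target window: ``on_target_width`` bp immediately
    downstream of the protospacer.

    "Downstream" defaults to 3' of the protospacer on its own strand
    (``downstream="plus"`` always extends rightward).  Windows are
    clipped at chromosome bounds with a warning; a window entirely
    outside the chromosome is an error.
    """
    config = config or AnalysisConfig()
    w = config.on_target_width
    iv = sgrna.interval
    rightward = downstream == "plus" or sgrna.strand == "+"
    if rightward:
        start, end = iv.end, iv.end + w
    else:
        start, end = iv.start - w, iv.start
    clipped_start = max(0, start)
    clipped_end = min(end, chrom_size) if chrom_size is not None else end
    if clipped_start >= clipped_end:
        raise ValueError(f"on-target window of {sgrna.name!r} lies outside the chromosome")
    if (clipped_start, clipped_end) != (start, end):
        logger.warning(
            "on-target window of %s clipped to %s:%d-%d",
            sgrna.name, iv.chrom, clipped_start, clipped_end,
        )
    return GenomicInterval(iv.chrom, clipped_start, clipped_end, name=f"{sgrna.name}_on")


def matched_background(
    on_target_wt_mean: float,
    wt_tile_means: pd.DataFrame,
    config: AnalysisConfig | None = None,
    exclude: Sequence[GenomicInterval] = (),
    exclusion_radius: int = 0,
) -> pd.DataFrame:
    """Tiles whose WT mean lies within +/- ``match_tol`` of the on-target
    WT level, excluding tiles overlapping ``exclude`` (grown by
    ``exclusion_radius``).

    ``wt_tile_means`` is a tile-means frame (chrom, start, end, mean).
    """
    config = config or AnalysisConfig()
    sel = wt_tile_means[
        (wt_tile_means["mean"] - on_target_wt_mean).abs() <= config.match_tol
    ].copy()
    for iv in exclude:
        lo, hi = iv.start - exclusion_radius, iv.end + exclusion_radius
        sel = sel[~((sel["chrom"] == iv.chrom) & (sel["start"] < hi) & (sel["end"] > lo))]
    if len(sel) == 0:
        logger.warning("matched background is empty (target WT mean %.3f)", on_target_wt_mean)
    return sel.reset_index(drop=True)


def on_off_contrast(
    clones: Mapping[str, TimeCourse],
    sgrna: SgRNATarget,
    wt_calls: pd.DataFrame,
    config: AnalysisConfig | None = None,
    day: int | None = None,
    region: GenomicInterval | None = None,
    chrom_size: int | None = None,
) -> pd.DataFrame:
    """On-target vs methylation-matched off-target gain for one guide.

    For each clone: delta = mean(day d) - mean(day 0), for the literal
    on-target window and for every matched background tile; the
    off-target summary is the mean and SD of the background deltas.
    A final row aggregates mean +/- SD across clones (SD is NA for a
    single clone).

    ``wt_calls`` supplies the wild-type landscape used for matching;
    ``region`` optionally restricts the background universe (e.g. to the
    captured regions); ``day`` defaults to the last day of each series.
    """
    config = config or AnalysisConfig()
    window = on_target_tile(sgrna, config, chrom_size=chrom_size)
    wt_region = wt_calls
    if region is not None:
        wt_region = wt_calls[
            (wt_calls["chrom"] == region.chrom)
            & (wt_calls["pos"] >= region.start)
            & (wt_calls["pos"] < region.end)
        ]
    wt_tiles = tile_means(
        wt_region, config.tile_width, config.min_cov_summary, config.min_cpgs,
        read_weighted=config.read_weighted,
    )
    on_wt = tile_mean(window, wt_calls, config.min_cov_summary, config.read_weighted)
    if on_wt is None:
        raise ValueError(f"on-target window of {sgrna.name!r} has no covered WT CpGs")
    background = matched_background(on_wt, wt_tiles, config, exclude=[window])

    rows = []
    for clone, series in clones.items():
        days = sorted(series)
        d = day if day is not None else days[-1]
        if 0 not in series or d not in series:
            raise ValueError(f"clone {clone!r} must include day 0 and day {d}")
        on0 = tile_mean(window, series[0], config.min_cov_summary, config.read_weighted)
        on1 = tile_mean(window, series[d], config.min_cov_summary, config.read_weighted)
        on_delta = (on1 - on0) if on0 is not None and on1 is not None else float("nan")
        tm0 = tile_means(
            series[0], config.tile_width, config.min_cov_summary,
            read_weighted=config.read_weighted,
        )
        tm1 = tile_means(
            series[d], config.tile_width, config.min_cov_summary,
            read_weighted=config.read_weighted,
        )
        joined = background[["chrom", "start"]].merge(
            tm0[["chrom", "start", "mean"]], on=["chrom", "start"]
        ).merge(
            tm1[["chrom", "start", "mean"]], on=["chrom", "start"],
            suffixes=("_0", "_d"),
        )
        off = (joined["mean_d"] - joined["mean_0"]).to_numpy()
        rows.append(
            {
                "clone": clone,
                "day": d,
                "on_target_delta": on_delta,
                "off_target_mean_delta": float(off.mean()) if off.size else float("nan"),
                "off_target_sd_delta": float(off.std(ddof=1)) if off.size > 1 else float("nan"),
                "n_background_tiles": int(off.size),
            }
        )
    out = pd.DataFrame(rows)
    on_all = out["on_target_delta"].to_numpy(dtype=float)
    off_all = out["off_target_mean_delta"].to_numpy(dtype=float)
    summary = {
        "clone": "all",
        "day": out["day"].iloc[0] if len(out) else float("nan"),
        "on_target_delta": float(np.nanmean(on_all)) if len(out) else float("nan"),
        "off_target_mean_delta": float(np.nanmean(off_all)) if len(out) else float("nan"),
        "off_target_sd_delta": float(np.nanstd(off_all, ddof=1)) if len(out) > 1 else float("nan"),
        "on_target_sd_delta": float(np.nanstd(on_all, ddof=1)) if len(out) > 1 else float("nan"),
        "n_background_tiles": int(out["n_background_tiles"].iloc[0]) if len(out) else 0,
    }
    return pd.concat([out, pd.DataFrame([summary])], ignore_index=True)


def gain_curve(
    clones: Mapping[str, TimeCourse],
    regions: Sequence[GenomicInterval],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-day mean methylation (+/- SD across clones) over a common CpG set.

    The CpG set is the dyads inside ``regions`` covered by >=
    ``min_cov_summary`` reads in EVERY sample of EVERY clone, so each
    point of the curve averages exactly the same dyads.
    """
    config = config or AnalysisConfig()
    if not clones:
        raise ValueError("need at least one clone")
    common: set[tuple[str, int]] | None = None
    for series in clones.values():
        for calls in series.values():
            q = calls[calls["n_total"] >= config.min_cov_summary]
            keys = set(zip(q["chrom"], q["pos"]))
            common = keys if common is None else common & keys
    in_regions = set()
    for chrom, pos in common or ():
        for iv in regions:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                in_regions.add((chrom, pos))
                break
    if not in_regions:
        raise ValueError("no CpGs covered in all samples within the regions")

    days = sorted({d for series in clones.values() for d in series})
    rows = []
    for day in days:
        per_clone = []
        for clone, series in clones.items():
            if day not in series:
                continue
            calls = series[day]
            key = pd.MultiIndex.from_frame(calls[["chrom", "pos"]])
            sel = calls[key.isin(in_regions)]
            per_clone.append(float(sel["level"].mean()))
        arr = np.array(per_clone)
        rows.append(
            {
                "day": day,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                "n_clones": int(arr.size),
                "n_cpgs": len(in_regions),
            }
        )
    return pd.DataFrame(rows)


def top_k_overlap(
    samples: Mapping[str, pd.DataFrame],
    config: AnalysisConfig | None = None,
    k: int | None = None,
) -> tuple[dict[str, set[tuple[str, int]]], dict[frozenset, int]]:
    """Top-k most methylated tiles per sample and all intersection sizes.

    A tile is eligible only if it qualifies (>= min_cpgs covered dyads)
    in every sample.  Ranking is by mean level descending with ties
    broken by (chrom, start) ascending.  Returns (per-sample top-k tile
    key sets, {frozenset of sample names: intersection cardinality})
    for every subset of >= 2 samples.
    """
    config = config or AnalysisConfig()
    k = k or config.top_k
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    per_sample = {
        name: tile_means(
            calls, config.tile_width, config.min_cov_summary, config.min_cpgs,
            read_weighted=config.read_weighted,
        )
        for name, calls in samples.items()
    }
    eligible: set[tuple[str, int]] | None = None
    for tm in per_sample.values():
        keys = set(zip(tm["chrom"], tm["start"]))
        eligible = keys if eligible is None else eligible & keys
    eligible = eligible or set()
    if len(eligible) < k:
        logger.warning("only %d eligible tiles for top-%d selection", len(eligible), k)

    tops: dict[str, set[tuple[str, int]]] = {}
    for name, tm in per_sample.items():
        key = pd.MultiIndex.from_frame(tm[["chrom", "start"]])
        sub = tm[key.isin(eligible)].sort_values(
            ["mean", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
        )
        tops[name] = set(zip(sub["chrom"].head(k), sub["start"].head(k)))

    names = list(samples)
    overlaps: dict[frozenset, int] = {}
    from itertools import combinations

    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(tops[n] for n in combo))
            overlaps[frozenset(combo)] = len(inter)
    return tops, overlaps


def cgi_class_summary(
    calls_wt: pd.DataFrame,
    calls_sample: pd.DataFrame,
    cgi_intervals: Sequence[GenomicInterval],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Classify CGIs by wild-type mean (hyper > 0.8, hypo <= 0.2, else
    intermediate) and summarize each class in the test sample."""
    config = config or AnalysisConfig()
    rows = []
    for iv in cgi_intervals:
        wt = tile_mean(iv, calls_wt, config.min_cov_summary, config.read_weighted)
        if wt is None:
            continue
        if wt > config.cgi_hyper_cut:
            cls = "hyper"
        elif wt <= config.cgi_hypo_cut:
            cls = "hypo"
        else:
            cls = "intermediate"
        test = tile_mean(iv, calls_sample, config.min_cov_summary, config.read_weighted)
        rows.append(
            {
                "name": iv.name or f"{iv.chrom}:{iv.start}",
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "wt_mean": wt, "class": cls,
                "sample_mean": test if test is not None else float("nan"),
            }
        )
    per_cgi = pd.DataFrame(rows)
    if len(per_cgi) == 0:
        return pd.DataFrame(columns=["class", "n_cgis", "wt_mean", "sample_mean"])
    summary = per_cgi.groupby("class", as_index=False).agg(
        n_cgis=("name", "size"), wt_mean=("wt_mean", "mean"), sample_mean=("sample_mean", "mean")
    )
    summary.attrs["per_cgi"] = per_cgi
    return summary


def cgi_k4_score(
    cgi_intervals: Sequence[GenomicInterval],
    chip_counts: Sequence[int] | np.ndarray,
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """ChIP read counts per CGI scaled to a 0-100 H3K4me3 score.

    density = count / CGI length; the top-1% density (nearest-rank 99th
    percentile) maps to 100 and everything above it is capped.
    """
    config = config or AnalysisConfig()
    counts = np.asarray(chip_counts, dtype=float)
    if len(counts) != len(cgi_intervals):
        raise ValueError("one ChIP count per CGI required")
    if (counts < 0).any():
        raise ValueError("ChIP counts must be non-negative")
    lengths = np.array([len(iv) for iv in cgi_intervals], dtype=float)
    density = counts / lengths
    if density.size == 0 or density.max() == 0:
        return np.zeros_like(density)
    # nearest-rank percentile: smallest value with cumulative rank >= q
    sorted_d = np.sort(density)
    rank = int(np.ceil(config.chip_top_quantile * density.size))
    q = sorted_d[max(0, rank - 1)]
    if q == 0:
        q = density.max()
    return np.minimum(100.0, 100.0 * density / q)


def delta_histogram(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    config: AnalysisConfig | None = None,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Histogram of per-tile methylation deltas over 1 kb tiles.

    Tiles need >= ``min_cpgs`` qualifying dyads (>= ``min_cov_summary``
    reads) in both samples.  Bins are left-closed right-open with width
    0.05 spanning [-1, 1]; a delta exactly on an edge falls in the bin
    whose left edge it is.
    """
    config = config or AnalysisConfig()
    w = config.delta_tile_width
    ta = tile_means(calls_a, w, config.min_cov_summary, config.min_cpgs, config.read_weighted)
    tb = tile_means(calls_b, w, config.min_cov_summary, config.min_cpgs, config.read_weighted)
    merged = pd.merge(ta, tb, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    if len(merged) == 0:
        logger.warning("no qualifying 1 kb tiles for the delta histogram")
        counts = np.zeros(len(edges) - 1, dtype=int)
    else:
        delta = (merged["mean_b"] - merged["mean_a"]).to_numpy()
        idx = np.clip(np.floor((delta + 1.0) / bin_width).astype(int), 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def context_summary(
    calls_by_context: Mapping[str, pd.DataFrame],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Unweighted mean level per dinucleotide context (CG, CA, CC, CT).

    Contexts with no qualifying calls report NA.
    """
    config = config or AnalysisConfig()
    rows = []
    for context in ("CG", "CA", "CC", "CT"):
        calls = calls_by_context.get(context)
        if calls is None or len(calls) == 0:
            rows.append({"context": context, "n_sites": 0, "mean": float("nan")})
            continue
        q = calls[calls["n_total"] >= config.min_cov_summary]
        rows.append(
            {
                "context": context,
                "n_sites": int(len(q)),
                "mean": float(q["level"].mean()) if len(q) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def annotate_context(calls: pd.DataFrame, fasta_path: str) -> pd.DataFrame:
    """Attach a dinucleotide context column derived from a FASTA file."""
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    contexts = []
    for row in calls.itertuples(index=False):
        if row.chrom not in fa:
            raise ValueError(f"chromosome {row.chrom!r} missing from {fasta_path}")
        di = str(fa[row.chrom][row.pos : row.pos + 2]).upper()
        contexts.append(di if len(di) == 2 and di[0] == "C" else "NA")
    out = calls.copy()
    out["context"] = contexts
    return out
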