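"""Fixed-width genome tiling and per-tile / per-feature aggregation.

Tiles are [k*width, (k+1)*width) per chromosome with a trailing partial
tile, disjoint and covering the chromosome exactly.  A dyad belongs to
the tile containing its plus-strand C coordinate.  Tile means are the
unweighted mean of per-CpG levels among member dyads passing the
coverage filter (>= 5 reads by default); a read-weighted variant is
available behind ``read_weighted``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval

__all__ = ["make_tiles", "tile_of", "tile_means", "tile_mean", "intersect_feature"]


def make_tiles(chrom_sizes: dict[str, int], width: int) -> list[GenomicInterval]:
    """Partition each chromosome into width-bp tiles (last may be shorter)."""
    if width <= 0:
        raise ValueError(f"tile width must be positive, got {width}")
    tiles: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, width):
            tiles.append(GenomicInterval(chrom, start, min(start + width, size)))
    return tiles


def tile_of(pos: np.ndarray, width: int) -> np.ndarray:
    """Tile index (start // width) of each position."""
    return np.asarray(pos, dtype=np.int64) // width


def tile_means(
    calls: pd.DataFrame,
    width: int,
    min_cov: int = 5,
    min_cpgs: int = 1,
    read_weighted: bool = False,
) -> pd.DataFrame:
    """Per-tile summary over one sample's call table.

    Returns a DataFrame (chrom, start, end, n_cpgs, mean) with one row
    per tile containing >= ``min_cpgs`` dyads covered by >= ``min_cov``
    reads; other tiles are absent (missing).
    """
    q = calls[calls["n_total"] >= min_cov]
    if len(q) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "mean"])
    df = q.assign(start=tile_of(q["pos"].to_numpy(), width) * width)
    if read_weighted:
        grouped = df.groupby(["chrom", "start"], as_index=False).agg(
            n_cpgs=("pos", "size"), _nm=("n_meth", "sum"), _nt=("n_total", "sum")
        )
        grouped["mean"] = grouped["_nm"] / grouped["_nt"]
        grouped = grouped.drop(columns=["_nm", "_nt"])
    else:
        grouped = df.groupby(["chrom", "start"], as_index=False).agg(
            n_cpgs=("pos", "size"), mean=("level", "mean")
        )
    grouped = grouped[grouped["n_cpgs"] >= min_cpgs].copy()
    grouped["end"] = grouped["start"] + width
    return grouped[["chrom", "start", "end", "n_cpgs", "mean"]].reset_index(drop=True)


def tile_mean(
    tile: GenomicInterval,
    calls: pd.DataFrame,
    min_cov: int = 5,
    read_weighted: bool = False,
) -> float | None:
    """Mean level of one tile's qualifying dyads, or None if none qualify."""
    mask = (
        (calls["chrom"] == tile.chrom)
        & (calls["pos"] >= tile.start)
        & (calls["pos"] < tile.end)
        & (calls["n_total"] >= min_cov)
    )
    sub = calls[mask]
    if len(sub) == 0:
        return None
    if read_weighted:
        return float(sub["n_meth"].sum() / sub["n_total"].sum())
    return float(sub["level"].mean())


def _overlap_mask(calls: pd.DataFrame, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    """Boolean mask of calls overlapping any of the intervals."""
    mask = np.zeros(len(calls), dtype=bool)
    pos = calls["pos"].to_numpy()
    chroms = calls["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        p = pos[sel]
        order = np.argsort(p, kind="mergesort")
        p_sorted = p[order]
        hit = np.zeros(len(p), dtype=bool)
        for iv in intervals:
            if iv.chrom != chrom:
                continue
            lo = np.searchsorted(p_sorted, iv.start, side="left")
            hi = np.searchsorted(p_sorted, iv.end, side="left")
            hit[order[lo:hi]] = True
        mask[np.flatnonzero(sel)] = hit
    return mask


def intersect_feature(
    calls: pd.DataFrame,
    feature_classes: dict[str, Sequence[GenomicInterval]],
    min_cov: int = 5,
) -> pd.DataFrame:
    """Unweighted mean level per feature class.

    A dyad counts toward a class if it overlaps any interval of that
    class; classes with no qualifying dyads report NA.
    """
    q = calls[calls["n_total"] >= min_cov].reset_index(drop=True)
    rows = []
    for name, intervals in feature_classes.items():
        hit = _overlap_mask(q, intervals) if len(q) else np.zeros(0, dtype=bool)
        n = int(hit.sum())
        mean = float(q.loc[hit, "level"].mean()) if n else float("nan")
        rows.append({"feature": name, "n_cpgs": n, "mean": mean})
    return pd.DataFrame(rows)
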