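"""Readers and writers for the on-disk formats used throughout the package.

Per-CpG methylation calls travel in a bedGraph-like "coverage" dialect:
six tab-separated columns ``chrom  start  end  fraction  n_meth  n_unmeth``
with 0-based half-open coordinates.  The fraction column may be on a 0-1
or 0-100 scale; the scale is auto-detected per file and cross-checked
against the counts.  Region annotations are plain BED3/BED6.  All output
files are TSV; header lines begin with ``#``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "SgRNATarget",
    "FormatError",
    "IntegrityError",
    "read_call_table",
    "write_call_table",
    "read_bed",
    "write_bed",
    "read_sgrnas",
    "read_chip_counts",
    "read_reads_table",
    "write_reads_table",
    "write_fasta",
]

#: columns of an in-memory call table (one row per CpG dyad or cytosine)
CALL_COLUMNS = ["chrom", "pos", "n_meth", "n_total", "level"]


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class IntegrityError(ValueError):
    """A file parses but its values contradict each other."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SgRNATarget:
    """A protospacer interval with mandatory strand."""

    name: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"sgRNA {self.name!r} needs strand '+' or '-', got {self.strand!r}")


# ---------------------------------------------------------------------------
# call tables


def read_call_table(
    path: str | Path,
    min_coverage: int = 0,
    stranded: bool = False,
) -> pd.DataFrame:
    """Read a coverage-dialect call table.

    Parameters
    ----------
    path
        Six (or seven, with a trailing strand column) tab-separated
        columns: chrom, start, end, fraction, n_meth, n_unmeth[, strand].
    min_coverage
        Records with n_meth + n_unmeth below this are dropped (the
        standard summary filter is >= 5 reads).
    stranded
        If False (default) and a strand column is present, the two
        strands of each dyad are merged onto the plus-strand coordinate
        by summing counts.

    Returns
    -------
    DataFrame with columns chrom, pos, n_meth, n_total, level, sorted by
    (chrom, pos).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CALL_COLUMNS).astype(
            {"pos": int, "n_meth": int, "n_total": int, "level": float}
        )
    if df.shape[1] not in (6, 7):
        raise FormatError(f"{path}: expected 6 or 7 columns, found {df.shape[1]}")
    has_strand = df.shape[1] == 7
    cols = ["chrom", "start", "end", "fraction", "n_meth", "n_unmeth"]
    if has_strand:
        cols.append("strand")
    df.columns = cols
    try:
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["start"].astype(np.int64),
                "fraction": df["fraction"].astype(float),
                "n_meth": df["n_meth"].astype(np.int64),
                "n_unmeth": df["n_unmeth"].astype(np.int64),
            }
        )
    except (ValueError, TypeError) as exc:
        bad = _first_bad_line(df)
        raise FormatError(f"{path}: malformed record at data line {bad}: {exc}") from exc

    if (out["n_meth"] < 0).any() or (out["n_unmeth"] < 0).any():
        bad = int(np.flatnonzero((out["n_meth"] < 0) | (out["n_unmeth"] < 0))[0]) + 1
        raise FormatError(f"{path}: negative count at data line {bad}")
    out["n_total"] = out["n_meth"] + out["n_unmeth"]
    if (out["n_total"] <= 0).any():
        bad = int(np.flatnonzero(out["n_total"] <= 0)[0]) + 1
        raise FormatError(f"{path}: zero-coverage record at data line {bad}")

    # fraction scale auto-detection: a file whose max fraction exceeds 1
    # is on the 0-100 percent scale
    frac = out["fraction"].to_numpy()
    if not np.isfinite(frac).all():
        bad = int(np.flatnonzero(~np.isfinite(frac))[0]) + 1
        raise FormatError(f"{path}: non-finite fraction at data line {bad}")
    if frac.size and np.nanmax(frac) > 1.0:
        frac = frac / 100.0
    level = out["n_meth"].to_numpy() / out["n_total"].to_numpy()
    mismatch = np.abs(frac - level) > 0.01
    if mismatch.any():
        bad = int(np.flatnonzero(mismatch)[0]) + 1
        raise IntegrityError(
            f"{path}: fraction/count mismatch at data line {bad} "
            f"(fraction {frac[mismatch][0]:.4f} vs counts {level[mismatch][0]:.4f})"
        )
    out["level"] = level

    if has_strand and not stranded:
        minus = df["strand"].to_numpy() == "-"
        # minus-strand C of a dyad sits at plus-strand position + 1
        out.loc[minus, "pos"] -= 1
        out = (
            out.groupby(["chrom", "pos"], as_index=False)[["n_meth", "n_total"]]
            .sum()
            .assign(level=lambda d: d["n_meth"] / d["n_total"])
        )

    out = out[out["n_total"] >= min_coverage]
    dup = out.duplicated(["chrom", "pos"])
    if dup.any():
        raise IntegrityError(f"{path}: duplicate (chrom, pos) records")
    return (
        out[CALL_COLUMNS]
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )


def _first_bad_line(df: pd.DataFrame) -> int:
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            int(row[1]), int(row[2]), float(row[3]), int(row[4]), int(row[5])
        except (ValueError, TypeError):
            return i
    return -1


def write_call_table(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a call table in the coverage dialect (fraction in [0,1], 6 dp)."""
    path = Path(path)
    if len(calls) == 0:
        path.write_text("")
        return
    with np.errstate(divide="ignore", invalid="ignore"):
        level = calls["n_meth"].to_numpy() / calls["n_total"].to_numpy()
    if not np.isfinite(level).all():
        raise IntegrityError("refusing to write non-finite fractions")
    if ((calls["n_meth"] < 0) | (calls["n_meth"] > calls["n_total"])).any():
        raise IntegrityError("refusing to write counts with n_meth outside [0, n_total]")
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"],
            "end": calls["pos"] + 1,
            "fraction": [f"{x:.6f}" for x in level],
            "n_meth": calls["n_meth"],
            "n_unmeth": calls["n_total"] - calls["n_meth"],
        }
    )
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tfraction\tn_meth\tn_unmeth\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED and annotation files


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals; overlaps are allowed but logged."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns, found {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else None
            intervals.append(GenomicInterval(parts[0], start, end, name=name, strand=strand))
    _warn_overlaps(path, intervals)
    return intervals


def _warn_overlaps(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                logger.warning("%s: overlapping intervals on %s at %d", path, chrom, b.start)
                return


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(fields) + "\n")


def read_sgrnas(path: str | Path, one_based: bool = False) -> list[SgRNATarget]:
    """Read protospacers from BED6 (or a 1-based inclusive TSV with
    ``one_based=True``, matching coordinates as printed in free text).

    Every record must carry a strand.
    """
    guides: list[SgRNATarget] = []
    for i, iv in enumerate(read_bed(path)):
        if iv.strand is None:
            raise FormatError(f"{path}: sgRNA record {i + 1} lacks a strand")
        start, end = iv.start, iv.end
        if one_based:
            start -= 1  # 1-based inclusive -> 0-based half-open
        guides.append(
            SgRNATarget(
                name=iv.name or f"sgRNA{i + 1}",
                interval=GenomicInterval(iv.chrom, start, end, name=iv.name),
                strand=iv.strand,
            )
        )
    return guides


def read_chip_counts(path: str | Path) -> pd.DataFrame:
    """Read per-CGI ChIP read counts: chrom, start, end, count TSV."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "count"],
    )
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative ChIP read count")
    return df


# ---------------------------------------------------------------------------
# read-level records


def read_reads_table(path: str | Path) -> pd.DataFrame:
    """Read read-level methylation records.

    Columns: read_id, chrom, sample, comma-separated dyad positions,
    comma-separated 0/1 states, strand.  Positions must be strictly
    increasing and match the states in length.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["read_id", "chrom", "sample", "positions", "states", "strand"],
            dtype=str,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["read_id", "chrom", "sample", "positions", "states", "strand"])
    positions, states = [], []
    for i, (p, s) in enumerate(zip(df["positions"], df["states"]), start=1):
        pos = np.fromstring(p, dtype=np.int64, sep=",")
        st = np.fromstring(s, dtype=np.int64, sep=",")
        if len(pos) != len(st):
            raise FormatError(f"{path}: read at data line {i}: positions/states length mismatch")
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise FormatError(f"{path}: read at data line {i}: positions not strictly increasing")
        if st.size and not np.isin(st, (0, 1)).all():
            raise FormatError(f"{path}: read at data line {i}: states must be 0/1")
        positions.append(pos)
        states.append(st)
    out = df[["read_id", "chrom", "sample", "strand"]].copy()
    out["positions"] = positions
    out["states"] = states
    return out


def write_reads_table(reads: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tsample\tpositions\tstates\tstrand\n")
        for row in reads.itertuples(index=False):
            fh.write(
                f"{row.read_id}\t{row.chrom}\t{row.sample}\t"
                f"{','.join(map(str, row.positions))}\t"
                f"{','.join(map(str, row.states))}\t{row.strand}\n"
            )


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
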