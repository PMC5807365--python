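"""Read-level "none"/"some" classification for hemimethylation detection.

Every read with at least one CpG dyad inside a window is classified
"none" if all its in-window calls are unmethylated and "some" if at
least one is methylated.  At a fully hemimethylated locus — methylation
on exactly one strand of every dyad — strand-uniform reads split 50/50
between the classes, the signature that distinguishes single-strand de
novo deposition (or a half-methylated cell population) from full
methylation of half the molecules at lower level.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io import GenomicInterval

__all__ = ["classify_reads", "hemimethylation_report"]


def classify_reads(
    reads: pd.DataFrame, windows: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per-window "none"/"some" counts over eligible reads.

    A read is eligible for a window if at least one of its dyads lies in
    [start, end); reads that merely overlap the interval with no
    in-window dyad carry no evidence and are excluded.  Returns one row
    per window: name, chrom, start, end, n_none, n_some, n_reads,
    fraction_some (NaN for windows with no eligible reads).
    """
    k = reads["positions"].map(len).to_numpy() if len(reads) else np.array([], dtype=int)
    read_idx = np.repeat(np.arange(len(reads)), k)
    pos_flat = (
        np.concatenate(list(reads["positions"])) if len(reads) else np.array([], dtype=np.int64)
    )
    state_flat = (
        np.concatenate(list(reads["states"])) if len(reads) else np.array([], dtype=np.int64)
    )
    chrom_flat = np.repeat(reads["chrom"].to_numpy() if len(reads) else np.array([]), k)

    rows = []
    for w in windows:
        m = (chrom_flat == w.chrom) & (pos_flat >= w.start) & (pos_flat < w.end)
        eligible = np.unique(read_idx[m])
        some = np.unique(read_idx[m & (state_flat == 1)])
        n_some = len(some)
        n = len(eligible)
        rows.append(
            {
                "name": w.name or f"{w.chrom}:{w.start}-{w.end}",
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_none": n - n_some,
                "n_some": n_some,
                "n_reads": n,
                "fraction_some": n_some / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def hemimethylation_report(
    reads: pd.DataFrame,
    windows: Sequence[GenomicInterval],
    ci_alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-window classification plus the pooled "some" fraction with a
    Wilson score confidence interval.

    Returns ``(per_window, pooled)`` where pooled has keys n_reads,
    n_some, fraction_some, ci_low, ci_high (NaN when no read is
    eligible anywhere).
    """
    per_window = classify_reads(reads, windows)
    n = int(per_window["n_reads"].sum()) if len(per_window) else 0
    n_some = int(per_window["n_some"].sum()) if len(per_window) else 0
    if n == 0:
        pooled = {
            "n_reads": 0,
            "n_some": 0,
            "fraction_some": float("nan"),
            "ci_low": float("nan"),
            "ci_high": float("nan"),
        }
    else:
        lo, hi = proportion_confint(n_some, n, alpha=ci_alpha, method="wilson")
        pooled = {
            "n_reads": n,
            "n_some": n_some,
            "fraction_some": n_some / n,
            "ci_low": float(lo),
            "ci_high": float(hi),
        }
    return per_window, pooled
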