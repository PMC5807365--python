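"""Synthetic methylome and bisulfite-observation simulator.

Emulates a methylation-depleted, maintenance-competent ES cell system
expressing a dCas9-coupled de novo methyltransferase:

* a synthetic genome with annotated CpG-island (CGI), bulk and
  enhancer-like compartments and a lattice CpG-dyad placement model with
  exactly binomial dyad counts per compartment;
* a bimodal wild-type methylation landscape (CGIs low, bulk high,
  enhancer-like tiles intermediate, a minority of methylated/K4-low
  CGIs), with per-CGI H3K4me3 density anti-correlated with methylation;
* per-day, per-cell, per-strand footprinting dynamics: global off-target
  gain whose susceptibility tracks the prior (wild-type) methylation
  state, sgRNA-directed on-target gain with exponential distance decay,
  H3K4me3 protection inside CGIs, and semiconservative division with
  DNMT1-style maintenance of hemimethylated CpG dyads;
* a binomial bisulfite observation layer with imperfect conversion,
  producing per-site call tables and per-read methylation records.

Each cell's chromosome is one DNA molecule, so a division inherits a
single parental strand per cell.  Unmaintained hemimethylation therefore
survives replication on a consistent strand within each cell — the state
that makes half of strand-uniform reads carry methylation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .config import AnalysisConfig, ConfigError, SimConfig
from .io import GenomicInterval, SgRNATarget

__all__ = [
    "SyntheticGenome",
    "TruthTable",
    "generate_genome",
    "assign_wt_landscape",
    "simulate_footprinting",
    "sample_reads",
    "make_hemimethylated_truth",
    "expected_gain_curve",
    "fit_off_target_rate",
    "observed_to_true_level",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# genome generation


@dataclass
class SyntheticGenome:
    """A single synthetic chromosome with dyad and compartment annotations."""

    chrom: str
    length: int
    sequence: np.ndarray  # dtype S1
    dyad_pos: np.ndarray  # plus-strand C coordinate of each CpG dyad, sorted
    cgi_intervals: list[GenomicInterval]
    enhancer_tiles: list[GenomicInterval]
    dyad_is_cgi: np.ndarray
    dyad_cgi_index: np.ndarray  # -1 outside CGIs
    dyad_is_enhancer: np.ndarray

    @property
    def n_dyads(self) -> int:
        return len(self.dyad_pos)

    def sequence_str(self) -> str:
        return self.sequence.tobytes().decode()

    def context_positions(self, context: str) -> np.ndarray:
        """Plus-strand cytosine positions whose dinucleotide is `context`."""
        if context == "CG":
            return self.dyad_pos
        if context not in ("CA", "CC", "CT"):
            raise ValueError(f"unknown context {context!r}")
        seq = self.sequence
        second = context[1].encode()
        mask = (seq[:-1] == b"C") & (seq[1:] == second)
        return np.flatnonzero(mask).astype(np.int64)


def _interval_membership(pos: np.ndarray, intervals: list[GenomicInterval]) -> np.ndarray:
    """Index of the covering interval for each position (-1 if none).

    Intervals must be disjoint.
    """
    idx = np.full(len(pos), -1, dtype=np.int64)
    for i, iv in enumerate(intervals):
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        idx[lo:hi] = i
    return idx


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Generate the synthetic chromosome, CpG dyads and compartments.

    Dyads are placed on a 2 bp candidate lattice: each even position is
    the plus-strand C of a dyad with probability 2x the per-bp rate of
    its compartment, so the dyad count per compartment is exactly
    binomial and no two dyads overlap.  The sequence is random ACGT with
    "CG" stamped at every dyad and accidental CG dinucleotides removed,
    so every CG in the sequence is an annotated dyad.
    """
    if config.genome_length <= 0:
        raise ConfigError("genome_length must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.genome_length

    # disjoint CGIs by rejection sampling
    lo, hi = config.cgi_length_range
    cgis: list[GenomicInterval] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(cgis) < config.n_cgis and attempts < config.n_cgis * 200:
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        if length >= L:
            continue
        start = int(rng.integers(0, L - length))
        if any(start < e and s < start + length for s, e in occupied):
            continue
        occupied.append((start, start + length))
        cgis.append(GenomicInterval(config.chrom, start, start + length, name=f"CGI_{len(cgis)}"))
    cgis.sort(key=lambda iv: iv.start)
    cgis = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"CGI_{i}")
        for i, iv in enumerate(cgis)
    ]

    # lattice dyad placement
    candidates = np.arange(0, L - 1, 2, dtype=np.int64)
    cgi_idx = _interval_membership(candidates, cgis)
    rate = np.where(cgi_idx >= 0, config.cpg_rate_cgi, config.cpg_rate_background)
    p = np.minimum(1.0, 2.0 * rate)
    keep = rng.random(len(candidates)) < p
    dyad_pos = candidates[keep]
    dyad_cgi_index = cgi_idx[keep]

    # sequence: random bases, stamp CG at dyads, strip accidental CGs
    seq = _BASES[rng.integers(0, 4, L)].copy()
    seq[dyad_pos] = b"C"
    seq[dyad_pos + 1] = b"G"
    is_dyad_start = np.zeros(L, dtype=bool)
    is_dyad_start[dyad_pos] = True
    accidental = (seq[:-1] == b"C") & (seq[1:] == b"G") & ~is_dyad_start[:-1]
    seq[np.flatnonzero(accidental) + 1] = b"A"

    # enhancer-like minority of non-CGI 200 bp tiles
    tile_starts = np.arange(0, L, 200, dtype=np.int64)
    tile_ends = np.minimum(tile_starts + 200, L)
    cgi_starts = np.array([iv.start for iv in cgis], dtype=np.int64)
    cgi_ends = np.array([iv.end for iv in cgis], dtype=np.int64)
    if len(cgis):
        overlaps = (tile_starts[:, None] < cgi_ends[None, :]) & (
            cgi_starts[None, :] < tile_ends[:, None]
        )
        non_cgi = ~overlaps.any(axis=1)
    else:
        non_cgi = np.ones(len(tile_starts), dtype=bool)
    eligible = np.flatnonzero(non_cgi)
    n_enh = int(round(config.enhancer_fraction * len(eligible)))
    enh_idx = np.sort(rng.choice(eligible, size=n_enh, replace=False)) if n_enh else np.array([], dtype=int)
    enhancer_tiles = [
        GenomicInterval(config.chrom, int(tile_starts[i]), int(tile_ends[i]), name=f"ENH_{j}")
        for j, i in enumerate(enh_idx)
    ]
    dyad_is_enhancer = np.zeros(len(dyad_pos), dtype=bool)
    if len(enhancer_tiles):
        enh_membership = _interval_membership(dyad_pos, enhancer_tiles)
        dyad_is_enhancer = enh_membership >= 0

    return SyntheticGenome(
        chrom=config.chrom,
        length=L,
        sequence=seq,
        dyad_pos=dyad_pos,
        cgi_intervals=cgis,
        enhancer_tiles=enhancer_tiles,
        dyad_is_cgi=dyad_cgi_index >= 0,
        dyad_cgi_index=dyad_cgi_index,
        dyad_is_enhancer=dyad_is_enhancer,
    )


# ---------------------------------------------------------------------------
# truth table


@dataclass
class TruthTable:
    """Ground-truth methylation state of a population of cells on one day.

    ``state`` has shape (n_dyads, n_cells, 2); the last axis is
    (plus strand, minus strand).  ``ca_state`` (shape (n_ca, n_cells)) is
    allocated only in ``cpg_and_cpa`` context mode and tracks plus-strand
    CpA cytosines; non-CpG methylation is not maintained through
    division.
    """

    genome: SyntheticGenome
    day: int
    baseline: np.ndarray  # day-0 methylation probability per dyad
    wt_baseline: np.ndarray  # pre-depletion (wild-type) probability
    susceptibility: np.ndarray  # effective off-target susceptibility per dyad
    k4_density: np.ndarray  # per dyad, 0 outside CGIs
    k4_protection_mult: np.ndarray  # 1 - k4_protection * normalized k4 (1 outside CGIs)
    cgi_k4: np.ndarray  # per CGI
    cgi_class_hyper: np.ndarray  # per CGI: forced WT-methylated islands
    state: np.ndarray  # bool (n_dyads, n_cells, 2)
    ca_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    ca_state: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.state.shape[1]

    def copy(self, day: int | None = None) -> "TruthTable":
        return dataclasses.replace(
            self,
            day=self.day if day is None else day,
            state=self.state.copy(),
            ca_state=None if self.ca_state is None else self.ca_state.copy(),
        )

    def true_fraction(self) -> np.ndarray:
        """Per-dyad true methylated-strand fraction in [0, 1]."""
        return self.state.mean(axis=(1, 2))

    def strand_fractions(self) -> tuple[np.ndarray, np.ndarray]:
        return self.state[:, :, 0].mean(axis=1), self.state[:, :, 1].mean(axis=1)

    def global_fraction(self) -> float:
        return float(self.state.mean()) if self.state.size else float("nan")

    def ca_fraction(self) -> float:
        if self.ca_state is None or self.ca_state.size == 0:
            return 0.0
        return float(self.ca_state.mean())

    def hemi_mask(self) -> np.ndarray:
        """(n_dyads, n_cells) mask of dyads with exactly one methylated strand."""
        return self.state.sum(axis=2) == 1

    def to_frame(self) -> pd.DataFrame:
        """Per-dyad truth summary (one row per dyad) for the truth TSV."""
        plus, minus = self.strand_fractions()
        return pd.DataFrame(
            {
                "chrom": self.genome.chrom,
                "pos": self.genome.dyad_pos,
                "context": "CG",
                "day": self.day,
                "true_fraction_plus": plus,
                "true_fraction_minus": minus,
                "is_cgi": self.genome.dyad_is_cgi.astype(int),
                "is_enhancer": self.genome.dyad_is_enhancer.astype(int),
                "k4_density": self.k4_density,
            }
        )


def assign_wt_landscape(
    genome: SyntheticGenome, config: SimConfig, rng: np.random.Generator | None = None
) -> TruthTable:
    """Draw the day-0 landscape and initialize the cell population.

    Baselines come from compartment-specific Beta distributions: CGIs
    low (a forced ``hyper_cgi_fraction`` minority high), bulk genome
    high, enhancer-like tiles intermediate.  Per-CGI H3K4me3 density is
    anti-correlated with the island's baseline.  In ``depleted`` mode
    all baselines are scaled so the global mean equals
    ``depleted_global_mean``; susceptibility to later off-target gain
    keeps tracking the unscaled wild-type baseline.  Dyads start
    strand-symmetric (mm with probability = baseline, else uu).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = genome.n_dyads
    n_cgi = len(genome.cgi_intervals)

    cgi_hyper = rng.random(n_cgi) < config.hyper_cgi_fraction if n_cgi else np.zeros(0, dtype=bool)
    wt = rng.beta(8.5, 1.5, n)  # bulk: high, mean ~0.85
    enh = genome.dyad_is_enhancer & ~genome.dyad_is_cgi
    wt[enh] = rng.beta(5.0, 5.0, int(enh.sum()))  # intermediate, centered 0.5
    in_cgi = genome.dyad_is_cgi
    cgi_idx = genome.dyad_cgi_index[in_cgi]
    hypo_dyads = ~cgi_hyper[cgi_idx] if n_cgi else np.zeros(0, dtype=bool)
    cgi_vals = np.empty(int(in_cgi.sum()))
    cgi_vals[hypo_dyads] = rng.beta(2.0, 38.0, int(hypo_dyads.sum()))  # mean 0.05
    cgi_vals[~hypo_dyads] = rng.beta(27.0, 3.0, int((~hypo_dyads).sum()))  # mean 0.90
    wt[in_cgi] = cgi_vals

    # per-CGI H3K4me3 density anti-correlated with its WT baseline
    cgi_k4 = np.zeros(n_cgi)
    if n_cgi:
        cgi_mean_wt = np.zeros(n_cgi)
        counts = np.bincount(cgi_idx, minlength=n_cgi).astype(float)
        sums = np.bincount(cgi_idx, weights=wt[in_cgi], minlength=n_cgi)
        nonempty = counts > 0
        cgi_mean_wt[nonempty] = sums[nonempty] / counts[nonempty]
        cgi_mean_wt[~nonempty] = np.where(cgi_hyper[~nonempty], 0.9, 0.05)
        cgi_k4 = np.clip(1.0 - cgi_mean_wt + rng.normal(0.0, 0.03, n_cgi), 0.0, 1.0)
    k4_density = np.zeros(n)
    k4_density[in_cgi] = cgi_k4[cgi_idx]

    baseline = wt.copy()
    if config.wt_mode == "depleted" and n and wt.mean() > 0:
        baseline = wt * min(1.0, config.depleted_global_mean / wt.mean())

    susceptibility = config.susceptibility_floor + (1.0 - config.susceptibility_floor) * wt
    protection = np.ones(n)
    if n_cgi and cgi_k4.max() > 0:
        k4_norm = k4_density / cgi_k4.max()
        protection = np.where(in_cgi, 1.0 - config.k4_protection * k4_norm, 1.0)
        susceptibility = susceptibility * protection

    state = np.zeros((n, config.n_cells, 2), dtype=bool)
    mm = rng.random((n, config.n_cells)) < baseline[:, None]
    state[:, :, 0] = mm
    state[:, :, 1] = mm

    ca_pos = np.array([], dtype=np.int64)
    ca_state = None
    if config.context_mode == "cpg_and_cpa":
        ca_pos = genome.context_positions("CA")
        ca_state = np.zeros((len(ca_pos), config.n_cells), dtype=bool)

    return TruthTable(
        genome=genome,
        day=0,
        baseline=baseline,
        wt_baseline=wt,
        susceptibility=susceptibility,
        k4_density=k4_density,
        k4_protection_mult=protection,
        cgi_k4=cgi_k4,
        cgi_class_hyper=cgi_hyper,
        state=state,
        ca_pos=ca_pos,
        ca_state=ca_state,
    )


# ---------------------------------------------------------------------------
# footprinting dynamics


def _on_target_rate(truth: "TruthTable", sgrnas: list[SgRNATarget], config: SimConfig) -> np.ndarray:
    """Per-dyad sgRNA-directed gain rate.

    The guide contributes the EXCESS of the on-target rate over the
    background process, max(0, r_on - r_off), modulated by the local
    H3K4me3 protection multiplier and an exponential distance decay
    inside the 2 kb window centered on the protospacer.  With
    r_on = r_off the guide term vanishes exactly, making the on-target
    window statistically exchangeable with its methylation-matched
    background; at the protospacer of an unprotected bulk locus the
    total rate approaches r_on.
    """
    genome = truth.genome
    rate = np.zeros(genome.n_dyads)
    excess = max(0.0, config.r_on - config.r_off)
    half = config.on_target_window / 2.0
    for g in sgrnas:
        if g.interval.chrom != genome.chrom:
            raise ValueError(
                f"sgRNA {g.name!r} on unknown chromosome {g.interval.chrom!r} "
                f"(genome has {genome.chrom!r})"
            )
        pos = genome.dyad_pos
        dist = np.maximum.reduce(
            [np.zeros(len(pos)), g.interval.start - pos, pos - (g.interval.end - 1)]
        )
        eligible = dist <= half
        rate += np.where(
            eligible,
            excess * truth.k4_protection_mult * np.exp(-dist / config.spread_lambda),
            0.0,
        )
    return rate


def _divide(
    state: np.ndarray,
    ca_state: np.ndarray | None,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """One semiconservative division in place, following one daughter per cell.

    The chromosome is one molecule, so each cell inherits a single
    parental strand (chosen at random); the complementary strand is
    synthesized unmethylated and DNMT1-style maintenance then fills in
    hemimethylated CpG dyads with probability ``maintenance_fidelity``.
    Non-CpG methylation is not a maintenance substrate.
    """
    n_cells = state.shape[1]
    inherited = rng.integers(0, 2, n_cells)  # 0 = plus strand kept, 1 = minus
    for s in (0, 1):
        cells = np.flatnonzero(inherited == s)
        if cells.size == 0:
            continue
        kept = state[:, cells, s]
        other = 1 - s
        if config.maintenance_on and config.maintenance_fidelity > 0:
            fill = kept & (rng.random(kept.shape) < config.maintenance_fidelity)
        else:
            fill = np.zeros_like(kept)
        state[:, cells, other] = fill
        if ca_state is not None:
            if s == 1:  # plus strand newly synthesized: plus-strand CpA lost
                ca_state[:, cells] = False


def simulate_footprinting(
    truth_day0: TruthTable,
    sgrnas: list[SgRNATarget],
    config: SimConfig,
    days: list[int],
    rng: np.random.Generator | None = None,
) -> dict[int, TruthTable]:
    """Advance the population day by day and snapshot the requested days.

    Each day, every unmethylated cytosine of an eligible context gains
    methylation on its strand with probability ``1 - exp(-rate)``, where
    rate = r_off * susceptibility + sum_g r_on * exp(-dist/lambda) inside
    the 2 kb guide window; gains precede the day's division(s).
    """
    if not days or days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be sorted ascending and start at 0")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    genome = truth_day0.genome

    rate = config.r_off * truth_day0.susceptibility + _on_target_rate(truth_day0, sgrnas, config)
    p_gain = 1.0 - np.exp(-rate)
    p_gain_ca = 1.0 - np.exp(-config.r_off * config.cpa_relative_rate)

    current = truth_day0.copy()
    snapshots: dict[int, TruthTable] = {}
    if 0 in days:
        snapshots[0] = current.copy(day=0)
    for day in range(1, max(days) + 1):
        # gain step (per strand, per cell)
        unmeth = ~current.state
        gains = rng.random(current.state.shape) < p_gain[:, None, None]
        current.state |= unmeth & gains
        if config.context_mode == "cpg_and_cpa" and current.ca_state is not None:
            ca_gains = rng.random(current.ca_state.shape) < p_gain_ca
            current.ca_state |= ~current.ca_state & ca_gains
        # division step(s)
        for _ in range(config.divisions_per_day):
            _divide(current.state, current.ca_state, config, rng)
        if day in days:
            snapshots[day] = current.copy(day=day)
    return snapshots


def make_hemimethylated_truth(
    genome: SyntheticGenome,
    config: SimConfig,
    window: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Construct a truth table whose dyads (within ``window``, default all)
    are fully hemimethylated.

    The methylated strand is chosen per cell and is the same for every
    dyad of that cell — the state left behind when de novo methylation on
    random strands passes through one unmaintained replication.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    n = genome.n_dyads
    zeros = np.zeros(n)
    state = np.zeros((n, config.n_cells, 2), dtype=bool)
    if window is None:
        in_window = np.ones(n, dtype=bool)
    else:
        in_window = (genome.dyad_pos >= window[0]) & (genome.dyad_pos < window[1])
    strand = rng.integers(0, 2, config.n_cells)
    for s in (0, 1):
        cells = np.flatnonzero(strand == s)
        state[np.ix_(np.flatnonzero(in_window), cells, [s])] = True
    n_cgi = len(genome.cgi_intervals)
    return TruthTable(
        genome=genome,
        day=0,
        baseline=zeros,
        wt_baseline=zeros.copy(),
        susceptibility=zeros.copy(),
        k4_density=zeros.copy(),
        k4_protection_mult=np.ones(n),
        cgi_k4=np.zeros(n_cgi),
        cgi_class_hyper=np.zeros(n_cgi, dtype=bool),
        state=state,
    )


# ---------------------------------------------------------------------------
# bisulfite observation layer


def sample_reads(
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample: str = "sample",
    emit_reads: bool = False,
) -> tuple[pd.DataFrame | None, dict[str, pd.DataFrame]]:
    """Sample bisulfite reads and aggregate per-site calls.

    Reads draw (cell, strand, start) uniformly; the read count is
    ``round(coverage * genome_length / read_length)``.  A methylated
    cytosine is reported methylated with ``protection_rate``; an
    unmethylated one with ``1 - conversion_rate``.  Per-site counts merge
    both strands of a dyad onto the plus-strand coordinate.

    Returns ``(reads, calls)`` where ``reads`` is a read-level record
    table (or None unless ``emit_reads``) covering CG dyads, and
    ``calls`` maps each emitted context to a call table.
    """
    if config.coverage <= 0:
        raise ConfigError("coverage must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    genome = truth.genome
    L, rl = genome.length, config.read_length
    n_reads = int(round(config.coverage * L / rl))
    starts = rng.integers(0, max(1, L - rl + 1), n_reads)
    cells = rng.integers(0, truth.n_cells, n_reads)
    strands = rng.integers(0, 2, n_reads)

    calls: dict[str, pd.DataFrame] = {}
    reads_df: pd.DataFrame | None = None

    # --- CG dyads (strand-resolved truth)
    dyads = genome.dyad_pos
    lo = np.searchsorted(dyads, starts)
    hi = np.searchsorted(dyads, starts + rl - 1)
    k = hi - lo
    total = int(k.sum())
    read_rep = np.repeat(np.arange(n_reads), k)
    offsets = np.arange(total) - np.repeat(np.cumsum(k) - k, k)
    site_idx = np.repeat(lo, k) + offsets
    cell_rep = cells[read_rep]
    strand_rep = strands[read_rep]
    true_state = truth.state[site_idx, cell_rep, strand_rep]
    u = rng.random(total)
    obs = np.where(true_state, u < config.protection_rate, u < 1.0 - config.conversion_rate)

    n_sites = len(dyads)
    nm = np.bincount(site_idx, weights=obs, minlength=n_sites)
    nt = np.bincount(site_idx, minlength=n_sites)
    covered = nt > 0
    calls["CG"] = pd.DataFrame(
        {
            "chrom": genome.chrom,
            "pos": dyads[covered],
            "n_meth": nm[covered].astype(np.int64),
            "n_total": nt[covered].astype(np.int64),
            "level": nm[covered] / nt[covered],
        }
    )

    if emit_reads:
        bounds = np.cumsum(k)[:-1]
        pos_split = np.split(dyads[site_idx], bounds)
        obs_split = np.split(obs.astype(np.int64), bounds)
        nonempty = k > 0
        reads_df = pd.DataFrame(
            {
                "read_id": [f"{sample}_r{i}" for i in np.flatnonzero(nonempty)],
                "chrom": genome.chrom,
                "sample": sample,
                "positions": [pos_split[i] for i in np.flatnonzero(nonempty)],
                "states": [obs_split[i] for i in np.flatnonzero(nonempty)],
                "strand": np.where(strands[nonempty] == 0, "+", "-"),
            }
        )

    # --- non-CG contexts
    starts_sorted = np.sort(starts)
    for context in config.emit_contexts:
        if context == "CG":
            continue
        pos = genome.context_positions(context)
        if len(pos) == 0:
            continue
        # depth at a site = reads whose start lies in (pos - rl + 1, pos]
        depth = np.searchsorted(starts_sorted, pos, side="right") - np.searchsorted(
            starts_sorted, pos - rl + 1, side="left"
        )
        if context == "CA" and truth.ca_state is not None and len(truth.ca_pos) == len(pos):
            c_lo = np.searchsorted(pos, starts)
            c_hi = np.searchsorted(pos, starts + rl - 1)
            ck = c_hi - c_lo
            ctotal = int(ck.sum())
            c_read = np.repeat(np.arange(n_reads), ck)
            c_off = np.arange(ctotal) - np.repeat(np.cumsum(ck) - ck, ck)
            c_site = np.repeat(c_lo, ck) + c_off
            c_true = truth.ca_state[c_site, cells[c_read]]
            cu = rng.random(ctotal)
            c_obs = np.where(c_true, cu < config.protection_rate, cu < 1.0 - config.conversion_rate)
            nmx = np.bincount(c_site, weights=c_obs, minlength=len(pos))
            ntx = np.bincount(c_site, minlength=len(pos))
        else:
            ntx = depth
            nmx = rng.binomial(depth, 1.0 - config.conversion_rate)
        cov = ntx > 0
        calls[context] = pd.DataFrame(
            {
                "chrom": genome.chrom,
                "pos": pos[cov],
                "n_meth": np.asarray(nmx)[cov].astype(np.int64),
                "n_total": np.asarray(ntx)[cov].astype(np.int64),
                "level": np.asarray(nmx)[cov] / np.asarray(ntx)[cov],
            }
        )
    return reads_df, calls


# ---------------------------------------------------------------------------
# closed-form expectation and rate recovery


def expected_gain_curve(
    r_off: float,
    days: list[int],
    susceptibility: np.ndarray,
    baseline: np.ndarray,
    config: SimConfig,
) -> dict[int, float]:
    """Deterministic expectation of the genome-wide methylated-strand
    fraction under the simulator's update rules (no sgRNA term).

    Tracks, per dyad, the distribution over the number of methylated
    strands (0, 1 or 2): a gain step with per-strand probability
    ``g = 1 - exp(-r_off * s)`` followed by the division/maintenance
    step, whose one-daughter marginal is
    p0' = q0 + q1/2, p1' = (1-f)(q1/2 + q2), p2' = f(q1/2 + q2).
    """
    f = config.maintenance_fidelity if config.maintenance_on else 0.0
    g = 1.0 - np.exp(-r_off * susceptibility)
    p0 = 1.0 - baseline
    p1 = np.zeros_like(baseline)
    p2 = baseline.astype(float).copy()
    out: dict[int, float] = {}
    if 0 in days:
        out[0] = float(np.mean((p1 + 2.0 * p2) / 2.0))
    for day in range(1, max(days) + 1 if days else 0):
        q0 = p0 * (1.0 - g) ** 2
        q1 = p0 * 2.0 * g * (1.0 - g) + p1 * (1.0 - g)
        q2 = p0 * g**2 + p1 * g + p2
        p0, p1, p2 = q0, q1, q2
        for _ in range(config.divisions_per_day):
            hemi_pool = p1 / 2.0 + p2
            p0 = p0 + p1 / 2.0
            p1 = (1.0 - f) * hemi_pool
            p2 = f * hemi_pool
        if day in days:
            out[day] = float(np.mean((p1 + 2.0 * p2) / 2.0))
    return out


def observed_to_true_level(observed: np.ndarray | float, config: SimConfig):
    """Invert the bisulfite error model: E[obs] = t*prot + (1-t)*(1-conv)."""
    floor = 1.0 - config.conversion_rate
    denom = config.protection_rate - floor
    return np.clip((np.asarray(observed, dtype=float) - floor) / denom, 0.0, 1.0)


def fit_off_target_rate(
    days: list[int],
    observed_means: dict[int, float],
    susceptibility: np.ndarray,
    baseline: np.ndarray,
    config: SimConfig,
    r_max: float = 2.0,
) -> float:
    """Recover the off-target gain rate from an observed gain curve.

    Least-squares fit of :func:`expected_gain_curve` (after inverting the
    conversion/protection error model on the observations) over r_off.
    Susceptibility and baseline are known covariate fields: in the real
    assay they are the measurable wild-type methylation landscape.
    """
    days = sorted(observed_means)
    target = observed_to_true_level(np.array([observed_means[d] for d in days]), config)

    def loss(r: float) -> float:
        exp = expected_gain_curve(r, days, susceptibility, baseline, config)
        return float(np.sum((np.array([exp[d] for d in days]) - target) ** 2))

    res = optimize.minimize_scalar(loss, bounds=(0.0, r_max), method="bounded")
    return float(res.x)
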