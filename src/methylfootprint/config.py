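"""Configuration objects for the simulator and the analysis pipeline.

Every threshold the analysis applies lives in :class:`AnalysisConfig`;
every generative parameter of the synthetic methylome lives in
:class:`SimConfig`.  Both round-trip through a single YAML file with
``simulation:`` and ``analysis:`` sections (see :func:`load_config`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["SimConfig", "AnalysisConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic methylome and bisulfite observation layer.

    The defaults emulate a methylation-depleted, maintenance-competent ES
    cell system (global CpG methylation ~0.04) expressing a dCas9-coupled
    de novo methyltransferase: a bimodal wild-type landscape (CpG islands
    low, bulk genome high, a minority of intermediate enhancer-like tiles),
    H3K4me3 anti-correlated with CGI methylation, sgRNA-directed on-target
    gain with exponential spreading, and globally distributed off-target
    gain whose susceptibility tracks the prior (wild-type) methylation
    state of each locus.
    """

    genome_length: int = 2_000_000  # bp
    n_cgis: int = 40
    cgi_length_range: tuple[int, int] = (500, 2000)  # bp
    cpg_rate_background: float = 0.01  # dyads per bp outside CGIs
    cpg_rate_cgi: float = 0.08  # dyads per bp inside CGIs
    enhancer_fraction: float = 0.05  # fraction of non-CGI 200 bp tiles
    hyper_cgi_fraction: float = 0.10  # minority of CGIs methylated in WT
    wt_mode: Literal["wild_type", "depleted"] = "depleted"
    depleted_global_mean: float = 0.04  # target global mean in depleted mode

    # footprinting dynamics (per strand, per day)
    r_off: float = 0.05  # off-target gain rate at a fully susceptible site
    r_on: float = 1.0  # on-target gain rate at the protospacer
    spread_lambda: float = 250.0  # bp, exponential decay of on-target rate
    on_target_window: int = 2000  # bp, eligibility window centered on guide
    k4_protection: float = 0.8  # suppression of gain at H3K4me3-high CGIs
    susceptibility_floor: float = 0.1  # residual susceptibility at WT=0 loci
    maintenance_fidelity: float = 0.95  # P(hemi -> full per division)
    divisions_per_day: int = 1
    maintenance_on: bool = True
    context_mode: Literal["cpg_only", "cpg_and_cpa"] = "cpg_only"
    cpa_relative_rate: float = 0.3  # CpA deposition rate relative to CpG

    # observation layer
    n_cells: int = 200
    coverage: float = 30.0  # mean read depth
    read_length: int = 150  # bp
    conversion_rate: float = 0.995  # P(unmethylated C read unmethylated)
    protection_rate: float = 0.995  # P(methylated C read methylated)
    emit_contexts: tuple[str, ...] = ("CG", "CA")

    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ConfigError(f"genome_length must be positive, got {self.genome_length}")
        if self.r_on < 0 or self.r_off < 0:
            raise ConfigError("gain rates must be non-negative")
        for name in (
            "cpg_rate_background",
            "cpg_rate_cgi",
            "enhancer_fraction",
            "hyper_cgi_fraction",
            "k4_protection",
            "susceptibility_floor",
            "maintenance_fidelity",
            "conversion_rate",
            "protection_rate",
            "cpa_relative_rate",
            "depleted_global_mean",
        ):
            _check_prob(name, getattr(self, name))
        if self.wt_mode not in ("wild_type", "depleted"):
            raise ConfigError(f"unknown wt_mode {self.wt_mode!r}")
        if self.context_mode not in ("cpg_only", "cpg_and_cpa"):
            raise ConfigError(f"unknown context_mode {self.context_mode!r}")
        lo, hi = self.cgi_length_range
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid cgi_length_range {self.cgi_length_range!r}")
        if self.coverage <= 0:
            raise ConfigError(f"coverage must be positive, got {self.coverage}")
        if self.read_length <= 1:
            raise ConfigError(f"read_length must be > 1, got {self.read_length}")
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        if self.divisions_per_day < 0:
            raise ConfigError("divisions_per_day must be >= 0")


@dataclass
class AnalysisConfig:
    """Every printed threshold of the analysis in one place.

    ``min_cov_summary``
        minimum reads for a CpG to enter any summary statistic (>=5 reads).
    ``min_cov_test``
        minimum reads (in both samples) for a CpG to enter a paired test.
    ``min_cpgs``
        minimum qualifying CpGs for a tile or CGI to be tested at all.
    ``alpha`` / ``min_delta``
        the dual significance rule: BH-adjusted p < alpha AND
        |delta| > min_delta (delta cutoff waived for per-CGI tests).
    ``match_tol``
        half-width of the methylation-matched off-target background
        (tiles within +/- match_tol of the on-target WT level).
    """

    min_cov_summary: int = 5
    min_cov_test: int = 10
    min_cpgs: int = 3
    tile_width: int = 200
    delta_tile_width: int = 1000
    alpha: float = 0.05
    min_delta: float = 0.10
    match_tol: float = 0.05
    top_k: int = 100
    cgi_hyper_cut: float = 0.8
    cgi_hypo_cut: float = 0.2
    chip_top_quantile: float = 0.99
    loess_span: float = 0.4
    on_target_width: int = 200
    gain_only: bool = False
    read_weighted: bool = False

    def __post_init__(self) -> None:
        for name in ("tile_width", "delta_tile_width", "on_target_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "alpha",
            "min_delta",
            "match_tol",
            "cgi_hyper_cut",
            "cgi_hypo_cut",
            "chip_top_quantile",
        ):
            _check_prob(name, getattr(self, name))
        if not 0.0 < self.loess_span <= 1.0:
            raise ConfigError(f"loess_span must be in (0, 1], got {self.loess_span}")
        if self.min_cpgs < 1 or self.top_k < 1:
            raise ConfigError("min_cpgs and top_k must be >= 1")


_TUPLE_FIELDS = {"cgi_length_range", "emit_contexts"}


def _from_mapping(cls, mapping: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and v is not None else v
        for k, v in mapping.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[SimConfig, AnalysisConfig]:
    """Load a YAML file with ``simulation:`` and ``analysis:`` sections.

    Missing sections fall back to defaults; unknown keys are rejected with
    the offending key names.  ``simulation.seed`` is mandatory.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.get("simulation", {}) or {}
    if "seed" not in sim_raw:
        raise ConfigError("simulation.seed is required for reproducible runs")
    sim = _from_mapping(SimConfig, sim_raw)
    analysis = _from_mapping(AnalysisConfig, raw.get("analysis", {}) or {})
    return sim, analysis


def dump_config(sim: SimConfig, analysis: AnalysisConfig, path: str | Path) -> None:
    """Write both configs to one YAML file (inverse of :func:`load_config`)."""
    payload = {
        "simulation": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(sim).items()
        },
        "analysis": dataclasses.asdict(analysis),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
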