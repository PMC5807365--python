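"""End-to-end orchestration: simulate, analyze, report.

``run_simulation`` writes a complete synthetic data set (genome FASTA,
annotation BEDs, per-day call tables, truth tables, read-level records,
per-CGI ChIP counts, and a manifest with checksums).
``run_footprint_analysis`` sequences the analysis stages over such a
data set and writes one TSV per stage plus a headline summary.  The
module also hosts the self-contained simulation experiments (null FDR,
hemimethylation recovery, off-target rate recovery, on/off-target
discrimination) used to validate the method end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diff, footprint, io, readlevel, sim, smooth, tiles
from .config import AnalysisConfig, SimConfig, dump_config

logger = logging.getLogger(__name__)

__all__ = [
    "run_simulation",
    "run_footprint_analysis",
    "validate_inputs",
    "default_sgrnas",
    "hemi_experiment",
    "null_fdr_experiment",
    "rate_recovery_experiment",
    "on_off_experiment",
]


# ---------------------------------------------------------------------------
# helpers


def default_sgrnas(
    genome: sim.SyntheticGenome,
    rng: np.random.Generator,
    n: int = 2,
    compartment: str = "bulk",
    length: int = 20,
) -> list[io.SgRNATarget]:
    """Place protospacers in the requested compartment.

    ``bulk`` avoids CGIs and enhancer tiles by 2 kb (a Dazl-like,
    WT-methylated context); ``cgi_hypo`` targets unmethylated islands
    (a Foxb1-like context).
    """
    margin = 2000
    forbidden = [(iv.start - margin, iv.end + margin) for iv in genome.cgi_intervals]
    forbidden += [(iv.start - margin, iv.end + margin) for iv in genome.enhancer_tiles]
    guides: list[io.SgRNATarget] = []
    attempts = 0
    while len(guides) < n and attempts < 10_000:
        attempts += 1
        if compartment == "cgi_hypo" and genome.cgi_intervals:
            iv = genome.cgi_intervals[int(rng.integers(0, len(genome.cgi_intervals)))]
            start = int((iv.start + iv.end) // 2)
        else:
            start = int(rng.integers(margin, genome.length - margin - length))
            if any(lo < start + length and start < hi for lo, hi in forbidden):
                continue
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        # the 200 bp downstream window must carry CpGs to be measurable
        if strand == "+":
            w_lo, w_hi = start + length, start + length + 200
        else:
            w_lo, w_hi = start - 200, start
        n_window_dyads = int(
            np.searchsorted(genome.dyad_pos, w_hi) - np.searchsorted(genome.dyad_pos, w_lo)
        )
        if n_window_dyads < 3:
            continue
        guides.append(
            io.SgRNATarget(
                name=f"guide{len(guides) + 1}",
                interval=io.GenomicInterval(genome.chrom, start, start + length),
                strand=strand,
            )
        )
    return guides


def _wt_truth(truth0: sim.TruthTable, config: SimConfig, rng: np.random.Generator) -> sim.TruthTable:
    """A wild-type observation of the same genome: states drawn from the
    unscaled WT baseline (strand-symmetric)."""
    wt = truth0.copy()
    mm = rng.random((truth0.genome.n_dyads, config.n_cells)) < truth0.wt_baseline[:, None]
    wt.state[:, :, 0] = mm
    wt.state[:, :, 1] = mm
    return wt


def global_observed_mean(calls: pd.DataFrame, min_cov: int = 5) -> float:
    """Unweighted mean level over sites covered by >= min_cov reads."""
    q = calls[calls["n_total"] >= min_cov]
    return float(q["level"].mean()) if len(q) else float("nan")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# simulation stage


def run_simulation(
    sim_config: SimConfig,
    out_dir: str | Path,
    analysis_config: AnalysisConfig | None = None,
    days: list[int] | None = None,
    sgrnas: list[io.SgRNATarget] | None = None,
    force: bool = False,
    emit_reads: bool = True,
) -> dict:
    """Simulate the full data set into ``out_dir`` and return the manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    analysis_config = analysis_config or AnalysisConfig()
    days = days if days is not None else [0, 1, 2, 3, 7]
    rng = np.random.default_rng(sim_config.seed)

    genome = sim.generate_genome(sim_config, rng)
    truth0 = sim.assign_wt_landscape(genome, sim_config, rng)
    if sgrnas is None:
        sgrnas = default_sgrnas(genome, rng, n=2, compartment="bulk")
    snapshots = sim.simulate_footprinting(truth0, sgrnas, sim_config, days, rng)

    io.write_fasta({genome.chrom: genome.sequence_str()}, out / "genome.fa")
    io.write_bed(genome.cgi_intervals, out / "cgi.bed")
    io.write_bed(genome.enhancer_tiles, out / "enhancers.bed")
    io.write_bed(
        [
            io.GenomicInterval(
                g.interval.chrom, g.interval.start, g.interval.end, name=g.name, strand=g.strand
            )
            for g in sgrnas
        ],
        out / "sgrnas.bed",
    )

    # wild-type observation for matching / classification
    wt = _wt_truth(truth0, sim_config, rng)
    _, wt_calls = sim.sample_reads(wt, sim_config, rng, sample="WT")
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    io.write_call_table(wt_calls["CG"], calls_dir / "WT_CG.cov")

    truth_frames = []
    last_day = max(days)
    for day in days:
        truth = snapshots[day]
        emit = emit_reads and day == last_day
        reads, calls = sim.sample_reads(
            truth, sim_config, rng, sample=f"day{day}", emit_reads=emit
        )
        for context, table in calls.items():
            io.write_call_table(table, calls_dir / f"day{day}_{context}.cov")
        if emit and reads is not None:
            io.write_reads_table(reads, out / f"reads_day{day}.tsv")
        truth_frames.append(truth.to_frame())
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )

    # per-CGI ChIP read counts emulating an H3K4me3 pull-down
    depth_per_bp = 0.5
    lengths = np.array([len(iv) for iv in genome.cgi_intervals])
    lam = truth0.cgi_k4 * lengths * depth_per_bp
    chip = rng.poisson(lam) if len(lam) else np.array([], dtype=int)
    with open(out / "chip_counts.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\tcount\n")
        for iv, c in zip(genome.cgi_intervals, chip):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{int(c)}\n")

    dump_config(sim_config, analysis_config, out / "config.yaml")
    files = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    manifest = {
        "seed": sim_config.seed,
        "days": days,
        "chrom": genome.chrom,
        "genome_length": genome.length,
        "n_dyads": genome.n_dyads,
        "sgrnas": [
            {"name": g.name, "chrom": g.interval.chrom, "start": g.interval.start,
             "end": g.interval.end, "strand": g.strand}
            for g in sgrnas
        ],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(sim_config).items()
        },
        "checksums": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# analysis stage


def run_footprint_analysis(
    sim_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run every analysis stage over a simulated data set.

    Writes one TSV per stage into ``out_dir`` and returns the headline
    summary table (also written as ``summary.tsv``).
    """
    config = config or AnalysisConfig()
    sim_dir, out = Path(sim_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "thresholds: min_cov_summary=%d min_cov_test=%d min_cpgs=%d tile=%d/%d "
        "alpha=%g min_delta=%g match_tol=%g top_k=%d cgi_cuts=%g/%g loess_span=%g",
        config.min_cov_summary, config.min_cov_test, config.min_cpgs,
        config.tile_width, config.delta_tile_width, config.alpha, config.min_delta,
        config.match_tol, config.top_k, config.cgi_hyper_cut, config.cgi_hypo_cut,
        config.loess_span,
    )
    with open(sim_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    days = manifest["days"]
    last = max(days)
    chrom_size = manifest["genome_length"]

    def stage(name):
        logger.info("stage: %s", name)

    calls = {
        d: io.read_call_table(sim_dir / "calls" / f"day{d}_CG.cov", config.min_cov_summary)
        for d in days
    }
    wt_calls = io.read_call_table(sim_dir / "calls" / "WT_CG.cov", config.min_cov_summary)
    cgis = io.read_bed(sim_dir / "cgi.bed")
    guides = io.read_sgrnas(sim_dir / "sgrnas.bed")
    summary_rows: list[dict] = []

    for d in days:
        summary_rows.append(
            {"metric": f"global_mean_day{d}", "value": global_observed_mean(calls[d], config.min_cov_summary)}
        )

    stage("tile_diff")
    tile_stats = diff.tile_diff(calls[0], calls[last], config)
    tile_stats.to_csv(out / "tile_diff.tsv", sep="\t", index=False)
    n_sig = int(tile_stats["significant"].sum()) if len(tile_stats) else 0
    summary_rows += [
        {"metric": "tiles_tested", "value": len(tile_stats)},
        {"metric": "tiles_significant", "value": n_sig},
        {"metric": "significant_tile_fraction",
         "value": n_sig / len(tile_stats) if len(tile_stats) else float("nan")},
    ]

    stage("cgi_diff")
    cgi_stats = diff.cgi_diff(calls[0], calls[last], cgis, config)
    cgi_stats.to_csv(out / "cgi_diff.tsv", sep="\t", index=False)
    summary_rows.append(
        {"metric": "cgis_significant",
         "value": int(cgi_stats["significant"].sum()) if len(cgi_stats) else 0}
    )

    stage("on_off_contrast")
    clones = {"clone1": calls}
    contrast_frames = []
    for g in guides:
        c = footprint.on_off_contrast(
            clones, g, wt_calls, config, day=last, chrom_size=chrom_size
        )
        c.insert(0, "sgrna", g.name)
        contrast_frames.append(c)
    contrast = pd.concat(contrast_frames, ignore_index=True)
    contrast.to_csv(out / "on_off_contrast.tsv", sep="\t", index=False)
    first = contrast[contrast["clone"] != "all"].iloc[0]
    summary_rows += [
        {"metric": "on_target_delta", "value": float(first["on_target_delta"])},
        {"metric": "off_target_mean_delta", "value": float(first["off_target_mean_delta"])},
    ]

    stage("gain_curve")
    regions = [
        io.GenomicInterval(
            g.interval.chrom,
            max(0, g.interval.start - 20_000),
            min(chrom_size, g.interval.end + 20_000),
        )
        for g in guides
    ]
    curve = footprint.gain_curve(clones, regions, config)
    curve.to_csv(out / "gain_curve.tsv", sep="\t", index=False)

    stage("top_k_overlap")
    _, overlaps = footprint.top_k_overlap(
        {f"day{d}": calls[d] for d in days if d > 0}, config
    )
    with open(out / "topk_overlap.tsv", "w") as fh:
        fh.write("#samples\toverlap\n")
        for key, v in sorted(overlaps.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            fh.write(f"{'+'.join(sorted(key))}\t{v}\n")

    stage("feature_means")
    enhancers = io.read_bed(sim_dir / "enhancers.bed") if (sim_dir / "enhancers.bed").exists() else []
    feature_classes = {"CGI": cgis, "enhancer_like": enhancers}
    feature_frames = []
    for d in (0, last):
        fm = tiles.intersect_feature(calls[d], feature_classes, config.min_cov_summary)
        fm.insert(0, "sample", f"day{d}")
        feature_frames.append(fm)
    pd.concat(feature_frames, ignore_index=True).to_csv(
        out / "feature_means.tsv", sep="\t", index=False
    )

    stage("cgi_class_summary")
    classes = footprint.cgi_class_summary(wt_calls, calls[last], cgis, config)
    classes.to_csv(out / "cgi_classes.tsv", sep="\t", index=False)

    stage("cgi_k4_score")
    chip = io.read_chip_counts(sim_dir / "chip_counts.tsv")
    chip_intervals = [
        io.GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in chip.itertuples()
    ]
    scores = footprint.cgi_k4_score(chip_intervals, chip["count"].to_numpy(), config)
    chip.assign(k4_score=scores).to_csv(out / "cgi_k4_scores.tsv", sep="\t", index=False)

    stage("delta_histogram")
    hist = footprint.delta_histogram(calls[0], calls[last], config)
    hist.to_csv(out / "delta_histogram.tsv", sep="\t", index=False)

    stage("context_summary")
    by_context = {"CG": calls[last]}
    for context in ("CA", "CC", "CT"):
        path = sim_dir / "calls" / f"day{last}_{context}.cov"
        if path.exists():
            by_context[context] = io.read_call_table(path, config.min_cov_summary)
    contexts = footprint.context_summary(by_context, config)
    contexts.to_csv(out / "context_summary.tsv", sep="\t", index=False)
    for row in contexts.itertuples(index=False):
        summary_rows.append({"metric": f"mean_level_{row.context}", "value": row.mean})

    stage("read_level")
    reads_path = sim_dir / f"reads_day{last}.tsv"
    if reads_path.exists() and n_sig:
        reads = io.read_reads_table(reads_path)
        sig = tile_stats[tile_stats["significant"]].copy()
        sig["abs_delta"] = sig["delta"].abs()
        top = sig.nlargest(20, "abs_delta")
        windows = [
            io.GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in top.itertuples()
        ]
        per_window, pooled = readlevel.hemimethylation_report(reads, windows)
        per_window.to_csv(out / "read_level.tsv", sep="\t", index=False)
        summary_rows.append({"metric": "fraction_some", "value": pooled["fraction_some"]})

    stage("smooth_track")
    region = regions[0]
    track_calls = calls[last][
        (calls[last]["chrom"] == region.chrom)
        & (calls[last]["pos"] >= region.start)
        & (calls[last]["pos"] < region.end)
    ]
    if len(track_calls) >= 5:
        track = smooth.loess_smooth(
            track_calls["pos"].to_numpy(), track_calls["level"].to_numpy(), config.loess_span
        )
        pd.DataFrame(
            {"pos": track.positions.astype(int), "fitted": track.fitted, "sd": track.sd}
        ).to_csv(out / "smoothed_track.tsv", sep="\t", index=False)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return summary


def validate_inputs(paths: list[str | Path]) -> pd.DataFrame:
    """Report-only format/invariant check of a set of input files."""
    rows = []
    for p in paths:
        p = Path(p)
        kind, ok, message = "unknown", True, ""
        try:
            if p.suffix in (".cov",):
                kind = "call_table"
                table = io.read_call_table(p)
                if len(table) == 0:
                    message = "empty call set"
            elif p.suffix == ".bed":
                kind = "bed"
                if not io.read_bed(p):
                    ok, message = True, "warning: empty BED"
            elif p.name.startswith("reads") and p.suffix == ".tsv":
                kind = "reads"
                io.read_reads_table(p)
            elif p.suffix in (".fa", ".fasta"):
                kind = "fasta"
                ok = p.read_text().startswith(">")
                message = "" if ok else "no FASTA header"
            else:
                kind = "tsv"
                pd.read_csv(p, sep="\t", comment="#")
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            ok, message = False, f"{type(exc).__name__}: {exc}"
        rows.append({"path": str(p), "kind": kind, "ok": ok, "message": message})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# self-contained validation experiments


def hemi_experiment(seed: int, n_reads: int = 2000) -> dict:
    """Hemimethylation recovery: a fully hemimethylated window read by
    strand-uniform reads should classify ~50% of reads as "some".

    Exactly ``n_reads`` reads carrying CpG evidence are classified (the
    observation layer is oversampled and trimmed, since reads without an
    in-window dyad carry no evidence either way).
    """
    L = 20_000
    read_length = 150
    cfg = SimConfig(
        genome_length=L,
        n_cgis=0,
        cpg_rate_background=0.015,
        enhancer_fraction=0.0,
        coverage=1.5 * n_reads * read_length / L,
        read_length=read_length,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    genome = sim.generate_genome(cfg, rng)
    truth = sim.make_hemimethylated_truth(genome, cfg, rng=rng)
    reads, _ = sim.sample_reads(truth, cfg, rng, emit_reads=True)
    reads = reads.head(n_reads)
    window = io.GenomicInterval(cfg.chrom, 0, L)
    _, pooled = readlevel.hemimethylation_report(reads, [window])
    return pooled


def null_fdr_experiment(
    seed: int,
    sim_config: SimConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
) -> float:
    """Fraction of tiles called significant between two independent read
    samplings of the same truth (no methylation difference)."""
    analysis_config = analysis_config or AnalysisConfig()
    cfg = sim_config or SimConfig(wt_mode="wild_type", emit_contexts=("CG",), seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    genome = sim.generate_genome(cfg, rng)
    truth = sim.assign_wt_landscape(genome, cfg, rng)
    _, calls_a = sim.sample_reads(truth, cfg, rng, sample="a")
    _, calls_b = sim.sample_reads(truth, cfg, rng, sample="b")
    stats = diff.tile_diff(calls_a["CG"], calls_b["CG"], analysis_config)
    if len(stats) == 0:
        return 0.0
    return float(stats["significant"].mean())


def rate_recovery_experiment(
    seed: int,
    r_off: float,
    days: tuple[int, ...] = (0, 1, 2, 3),
) -> dict:
    """Simulate off-target gain at a known rate and recover it from the
    observed genome-wide gain curve."""
    cfg = SimConfig(seed=seed, r_off=r_off, r_on=0.0, emit_contexts=("CG",))
    rng = np.random.default_rng(seed)
    genome = sim.generate_genome(cfg, rng)
    truth0 = sim.assign_wt_landscape(genome, cfg, rng)
    snapshots = sim.simulate_footprinting(truth0, [], cfg, list(days), rng)
    observed = {}
    for d in days:
        _, calls = sim.sample_reads(snapshots[d], cfg, rng, sample=f"day{d}")
        observed[d] = global_observed_mean(calls["CG"], 5)
    r_hat = sim.fit_off_target_rate(
        list(days), observed, truth0.susceptibility, truth0.baseline, cfg
    )
    return {
        "r_true": r_off,
        "r_hat": r_hat,
        "relative_error": abs(r_hat - r_off) / r_off,
        "observed": observed,
    }


def on_off_experiment(
    seed: int,
    r_on_factor: float,
    r_off: float = 0.05,
    days: tuple[int, ...] = (0, 1, 2, 3),
) -> dict:
    """On/off-target discrimination against the methylation-matched
    background for a single guide in a bulk locus.

    Returns the on-target delta, the matched-background mean/SD delta,
    and the z score of the on-target gain against that background.
    """
    cfg = SimConfig(seed=seed, r_off=r_off, r_on=r_on_factor * r_off, emit_contexts=("CG",))
    analysis = AnalysisConfig()
    rng = np.random.default_rng(seed)
    genome = sim.generate_genome(cfg, rng)
    truth0 = sim.assign_wt_landscape(genome, cfg, rng)
    guides = default_sgrnas(genome, rng, n=1, compartment="bulk")
    snapshots = sim.simulate_footprinting(truth0, guides, cfg, list(days), rng)
    wt = _wt_truth(truth0, cfg, rng)
    _, wt_calls = sim.sample_reads(wt, cfg, rng, sample="WT")
    series = {}
    for d in (0, max(days)):
        _, calls = sim.sample_reads(snapshots[d], cfg, rng, sample=f"day{d}")
        series[d] = calls["CG"]
    contrast = footprint.on_off_contrast(
        {"clone1": series}, guides[0], wt_calls["CG"], analysis,
        day=max(days), chrom_size=genome.length,
    )
    row = contrast[contrast["clone"] == "clone1"].iloc[0]
    z = (row["on_target_delta"] - row["off_target_mean_delta"]) / row["off_target_sd_delta"]
    return {
        "on_target_delta": float(row["on_target_delta"]),
        "off_target_mean_delta": float(row["off_target_mean_delta"]),
        "off_target_sd_delta": float(row["off_target_sd_delta"]),
        "n_background_tiles": int(row["n_background_tiles"]),
        "z": float(z),
    }
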