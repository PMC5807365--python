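"""Simulator: genome generation, landscape, dynamics, observation layer."""

import dataclasses

import numpy as np
import pytest

from methylfootprint import (
    ConfigError,
    GenomicInterval,
    SgRNATarget,
    SimConfig,
    assign_wt_landscape,
    generate_genome,
    make_hemimethylated_truth,
    sample_reads,
    simulate_footprinting,
)
from methylfootprint.sim import expected_gain_curve


def guide(chrom, start, end, strand="+", name="g"):
    return SgRNATarget(name=name, interval=GenomicInterval(chrom, start, end), strand=strand)


class TestGenerateGenome:
    def test_fixed_seed_reproduces_genome_and_annotations(self):
        cfg = SimConfig(genome_length=50_000, n_cgis=4, seed=1)
        g1 = generate_genome(cfg)
        g2 = generate_genome(cfg)
        assert np.array_equal(g1.sequence, g2.sequence)
        assert np.array_equal(g1.dyad_pos, g2.dyad_pos)
        assert [(iv.start, iv.end) for iv in g1.cgi_intervals] == [
            (iv.start, iv.end) for iv in g2.cgi_intervals
        ]

    def test_zero_rates_give_zero_dyads(self):
        cfg = SimConfig(
            genome_length=10_000, cpg_rate_background=0.0, cpg_rate_cgi=0.0, seed=1
        )
        assert generate_genome(cfg).n_dyads == 0

    def test_every_dyad_is_cg_and_cgis_disjoint(self, small_genome):
        seq = small_genome.sequence
        assert (seq[small_genome.dyad_pos] == b"C").all()
        assert (seq[small_genome.dyad_pos + 1] == b"G").all()
        # no unannotated CG dinucleotides
        cg = (seq[:-1] == b"C") & (seq[1:] == b"G")
        assert np.array_equal(np.flatnonzero(cg), small_genome.dyad_pos)
        ivs = sorted(small_genome.cgi_intervals, key=lambda iv: iv.start)
        assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_dyad_count_matches_lattice_binomial_expectation(self):
        # placement model: every even position is a dyad with prob 2*rate;
        # with no CGIs the count is Binomial(n_candidates, 2*rate)
        L, rate = 1_000_000, 0.01
        cfg = SimConfig(genome_length=L, n_cgis=0, cpg_rate_background=rate, seed=3)
        g = generate_genome(cfg)
        n_candidates = len(np.arange(0, L - 1, 2))
        p = 2 * rate
        mean = n_candidates * p
        sd = np.sqrt(n_candidates * p * (1 - p))
        assert abs(g.n_dyads - mean) < 5 * sd

    def test_non_positive_length_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(genome_length=0, seed=1)


class TestLandscape:
    def test_depleted_mode_global_mean_at_most_five_percent(self, small_truth):
        assert small_truth.global_fraction() <= 0.05

    def test_wild_type_cgi_classes_and_k4_anticorrelation(self):
        cfg = SimConfig(
            genome_length=400_000, n_cgis=30, wt_mode="wild_type",
            hyper_cgi_fraction=0.3, seed=5,
        )
        g = generate_genome(cfg, np.random.default_rng(5))
        truth = assign_wt_landscape(g, cfg, np.random.default_rng(6))
        hyper = truth.cgi_class_hyper
        assert hyper.any() and (~hyper).any()
        in_cgi = g.dyad_is_cgi
        for i in np.flatnonzero(hyper):
            dyads = in_cgi & (g.dyad_cgi_index == i)
            if dyads.any():
                assert truth.wt_baseline[dyads].mean() > 0.8
        hypo_k4_median = np.median(truth.cgi_k4[~hyper])
        assert (truth.cgi_k4[hyper] < hypo_k4_median).all()

    def test_zero_baseline_gives_all_uu(self, small_genome):
        cfg = SimConfig(genome_length=100_000, depleted_global_mean=0.0, seed=7)
        truth = assign_wt_landscape(small_genome, cfg, np.random.default_rng(1))
        assert truth.global_fraction() == 0.0


class TestDynamics:
    def test_null_rates_preserve_states_through_divisions(self, small_genome, small_truth):
        cfg = SimConfig(genome_length=100_000, r_off=0.0, r_on=0.0,
                        maintenance_fidelity=1.0, seed=7)
        snaps = simulate_footprinting(small_truth, [], cfg, [0, 7], np.random.default_rng(2))
        # perfect maintenance + no gain: per-dyad fractions unchanged
        np.testing.assert_allclose(
            snaps[7].true_fraction(), snaps[0].true_fraction(), atol=0
        )

    def test_closed_form_survival_without_maintenance(self, small_genome):
        # r_off = 0.1/day on fully susceptible, unmethylated dyads with no
        # divisions: per-strand methylated fraction after 2 days is
        # 1 - exp(-0.2), within 3 SD of the binomial expectation
        cfg = SimConfig(
            genome_length=100_000, r_off=0.1, r_on=0.0,
            maintenance_on=False, divisions_per_day=0, seed=7,
        )
        truth = assign_wt_landscape(small_genome, cfg, np.random.default_rng(1))
        truth.state[:] = False
        truth.susceptibility[:] = 1.0
        snaps = simulate_footprinting(truth, [], cfg, [0, 2], np.random.default_rng(3))
        p = 1 - np.exp(-0.2)
        n = truth.state.size
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(snaps[2].global_fraction() - p) < 3 * sd

    def test_cpg_only_mode_never_methylates_ca(self, small_genome):
        cfg = SimConfig(genome_length=100_000, context_mode="cpg_only", seed=7)
        truth = assign_wt_landscape(small_genome, cfg, np.random.default_rng(1))
        snaps = simulate_footprinting(truth, [], cfg, [0, 3], np.random.default_rng(4))
        assert snaps[3].ca_fraction() == 0.0

    def test_cpa_mode_accumulates_ca_methylation(self, small_genome):
        cfg = SimConfig(genome_length=100_000, context_mode="cpg_and_cpa", seed=7)
        truth = assign_wt_landscape(small_genome, cfg, np.random.default_rng(1))
        snaps = simulate_footprinting(truth, [], cfg, [0, 3], np.random.default_rng(4))
        assert snaps[0].ca_fraction() == 0.0
        assert snaps[3].ca_fraction() > 0.005

    def test_monotone_gain_with_maintenance(self, small_truth):
        cfg = SimConfig(genome_length=100_000, seed=7)
        days = [0, 1, 2, 3, 5, 7]
        snaps = simulate_footprinting(small_truth, [], cfg, days, np.random.default_rng(5))
        fractions = [snaps[d].global_fraction() for d in days]
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))

    def test_matches_markov_chain_expectation(self, small_genome):
        cfg = SimConfig(genome_length=100_000, r_off=0.08, seed=7)
        truth = assign_wt_landscape(small_genome, cfg, np.random.default_rng(1))
        days = [0, 2, 4]
        snaps = simulate_footprinting(truth, [], cfg, days, np.random.default_rng(6))
        expected = expected_gain_curve(0.08, days, truth.susceptibility, truth.baseline, cfg)
        for d in days[1:]:
            assert snaps[d].global_fraction() == pytest.approx(expected[d], abs=0.01)

    def test_unknown_sgrna_chromosome_rejected(self, small_truth):
        cfg = SimConfig(genome_length=100_000, seed=7)
        with pytest.raises(ValueError, match="chromosome"):
            simulate_footprinting(
                small_truth, [guide("chrX", 100, 120)], cfg, [0, 1], np.random.default_rng(1)
            )

    def test_unsorted_days_rejected(self, small_truth):
        cfg = SimConfig(genome_length=100_000, seed=7)
        with pytest.raises(ValueError, match="days"):
            simulate_footprinting(small_truth, [], cfg, [1, 0], np.random.default_rng(1))

    def test_on_target_gain_localizes_to_guide_window(self, small_genome):
        cfg = SimConfig(genome_length=100_000, r_off=0.0, r_on=1.0, seed=7)
        truth = assign_wt_landscape(small_genome, cfg, np.random.default_rng(1))
        truth.state[:] = False
        g = guide(small_genome.chrom, 50_000, 50_020)
        snaps = simulate_footprinting(truth, [g], cfg, [0, 3], np.random.default_rng(7))
        frac = snaps[3].true_fraction()
        pos = small_genome.dyad_pos
        near = np.abs(pos - 50_010) <= 500
        far = np.abs(pos - 50_010) > 2_000
        assert frac[near].mean() > 0.3
        assert frac[far].mean() < 0.02


class TestSampleReads:
    def test_all_unmethylated_reads_at_conversion_noise_floor(self, small_genome):
        cfg = SimConfig(genome_length=100_000, seed=7)
        truth = assign_wt_landscape(small_genome, cfg, np.random.default_rng(1))
        truth.state[:] = False
        _, calls = sample_reads(truth, cfg, np.random.default_rng(8))
        cg = calls["CG"]
        pooled = cg["n_meth"].sum() / cg["n_total"].sum()
        n = cg["n_total"].sum()
        sd = np.sqrt(0.005 * 0.995 / n)
        assert abs(pooled - 0.005) < 4 * sd

    def test_all_methylated_reads_at_protection_ceiling(self, small_genome):
        cfg = SimConfig(genome_length=100_000, seed=7)
        truth = assign_wt_landscape(small_genome, cfg, np.random.default_rng(1))
        truth.state[:] = True
        _, calls = sample_reads(truth, cfg, np.random.default_rng(9))
        cg = calls["CG"]
        pooled = cg["n_meth"].sum() / cg["n_total"].sum()
        assert pooled == pytest.approx(0.995, abs=0.003)

    def test_total_bases_match_requested_coverage(self, small_genome, small_truth):
        cfg = SimConfig(genome_length=100_000, coverage=12, seed=7)
        reads, _ = sample_reads(small_truth, cfg, np.random.default_rng(10), emit_reads=True)
        n_reads = round(cfg.coverage * cfg.genome_length / cfg.read_length)
        sequenced = n_reads * cfg.read_length
        assert abs(sequenced / cfg.genome_length - cfg.coverage) / cfg.coverage < 0.05

    def test_zero_coverage_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(coverage=0, seed=1)

    def test_seed_determinism_end_to_end(self):
        cfg = SimConfig(genome_length=50_000, seed=42)

        def run():
            rng = np.random.default_rng(cfg.seed)
            g = generate_genome(cfg, rng)
            t = assign_wt_landscape(g, cfg, rng)
            snaps = simulate_footprinting(t, [], cfg, [0, 2], rng)
            _, calls = sample_reads(snaps[2], cfg, rng)
            return calls["CG"]

        a, b = run(), run()
        assert a.equals(b)


class TestHemimethylatedConstruction:
    def test_all_dyads_hemi_with_per_cell_consistent_strand(self):
        cfg = SimConfig(genome_length=20_000, n_cgis=0, seed=3)
        g = generate_genome(cfg, np.random.default_rng(3))
        truth = make_hemimethylated_truth(g, cfg, rng=np.random.default_rng(4))
        assert truth.hemi_mask().all()
        per_cell_plus = truth.state[:, :, 0].mean(axis=0)
        assert np.isin(per_cell_plus, [0.0, 1.0]).all()

    def test_dynamics_route_to_hemi_state(self):
        # saturating gain then one unmaintained division leaves every
        # methylated dyad hemimethylated on the inherited strand
        cfg = SimConfig(
            genome_length=50_000, n_cgis=0, r_off=8.0, r_on=0.0,
            maintenance_on=False, divisions_per_day=1, seed=9,
        )
        g = generate_genome(cfg, np.random.default_rng(9))
        truth = assign_wt_landscape(g, cfg, np.random.default_rng(9))
        truth.state[:] = False
        truth.susceptibility[:] = 1.0
        snaps = simulate_footprinting(truth, [], cfg, [0, 1], np.random.default_rng(9))
        day1 = snaps[1]
        meth_per_dyad_cell = day1.state.sum(axis=2)
        assert (meth_per_dyad_cell <= 1).all()
        assert day1.hemi_mask().mean() > 0.95
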