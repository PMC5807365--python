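"""On/off-target windows, matched background, rankings, CGI summaries."""

import numpy as np
import pandas as pd
import pytest

from methylfootprint import (
    AnalysisConfig,
    GenomicInterval,
    SgRNATarget,
    cgi_class_summary,
    cgi_k4_score,
    context_summary,
    delta_histogram,
    gain_curve,
    matched_background,
    on_target_tile,
    top_k_overlap,
)

from conftest import make_calls


def guide(start, end, strand, chrom="chr1"):
    return SgRNATarget(name="g", interval=GenomicInterval(chrom, start, end), strand=strand)


class TestOnTargetTile:
    def test_plus_strand_window_extends_downstream(self):
        w = on_target_tile(guide(10_000, 10_020, "+"))
        assert (w.start, w.end) == (10_020, 10_220)

    def test_minus_strand_window_mirrors(self):
        w = on_target_tile(guide(10_000, 10_020, "-"))
        assert (w.start, w.end) == (9_800, 10_000)

    def test_plus_convention_ignores_strand(self):
        w = on_target_tile(guide(10_000, 10_020, "-"), downstream="plus")
        assert (w.start, w.end) == (10_020, 10_220)

    def test_window_clipped_at_chromosome_end_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            w = on_target_tile(guide(10_000, 10_020, "+"), chrom_size=10_070)
        assert (w.start, w.end) == (10_020, 10_070)
        assert any("clipped" in r.message for r in caplog.records)

    def test_window_outside_chromosome_is_error(self):
        with pytest.raises(ValueError):
            on_target_tile(guide(10_000, 10_020, "+"), chrom_size=10_020)


def tile_frame(means):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [200 * i for i in range(len(means))],
            "end": [200 * (i + 1) for i in range(len(means))],
            "n_cpgs": 5,
            "mean": means,
        }
    )


class TestMatchedBackground:
    def test_tolerance_band_selects_matching_tiles(self):
        tiles = tile_frame([0.32, 0.36, 0.50])
        out = matched_background(0.35, tiles, AnalysisConfig())
        assert list(out["start"]) == [0, 200]

    def test_on_target_tile_excluded_even_if_matching(self):
        tiles = tile_frame([0.35, 0.36])
        target = GenomicInterval("chr1", 0, 200)
        out = matched_background(0.35, tiles, AnalysisConfig(), exclude=[target])
        assert list(out["start"]) == [200]

    def test_zero_tolerance_without_exact_match_warns_empty(self, caplog):
        tiles = tile_frame([0.32, 0.50])
        with caplog.at_level("WARNING"):
            out = matched_background(0.35, tiles, AnalysisConfig(match_tol=0.0))
        assert len(out) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_every_returned_tile_satisfies_bound(self):
        rng = np.random.default_rng(0)
        tiles = tile_frame(rng.random(50))
        out = matched_background(0.4, tiles, AnalysisConfig())
        assert ((out["mean"] - 0.4).abs() <= 0.05 + 1e-15).all()


def ranked_sample(order, n_tiles=13, cov=20):
    """Call table whose tile means decrease along ``order``."""
    records = []
    for rank, tile_idx in enumerate(order):
        level = 1.0 - rank / (n_tiles + 1)
        for j in range(3):
            pos = tile_idx * 200 + 10 + j * 20
            records.append(("chr1", pos, round(level * cov), cov))
    return make_calls(records)


class TestTopKOverlap:
    def test_identical_samples_intersect_fully(self):
        s = ranked_sample(range(13))
        _, overlaps = top_k_overlap({"a": s, "b": s, "c": s}, AnalysisConfig(top_k=10))
        assert overlaps[frozenset({"a", "b", "c"})] == 10

    def test_constructed_seven_of_ten_overlap(self):
        a = ranked_sample(list(range(13)))           # top-10 = tiles 0..9
        b = ranked_sample(list(range(3, 13)) + [0, 1, 2])  # top-10 = tiles 3..12
        _, overlaps = top_k_overlap({"a": a, "b": b}, AnalysisConfig(top_k=10))
        assert overlaps[frozenset({"a", "b"})] == 7

    def test_sample_order_invariance_and_cap(self):
        a = ranked_sample(list(range(13)))
        b = ranked_sample(list(reversed(range(13))))
        _, o1 = top_k_overlap({"a": a, "b": b}, AnalysisConfig(top_k=10))
        _, o2 = top_k_overlap({"b": b, "a": a}, AnalysisConfig(top_k=10))
        assert o1 == o2
        assert all(v <= 10 for v in o1.values())

    def test_fewer_than_k_eligible_uses_all_with_warning(self, caplog):
        s = ranked_sample(range(5), n_tiles=5)
        with caplog.at_level("WARNING"):
            tops, overlaps = top_k_overlap({"a": s, "b": s}, AnalysisConfig(top_k=100))
        assert overlaps[frozenset({"a", "b"})] == 5
        assert any("eligible" in r.message for r in caplog.records)


class TestGainCurve:
    def _series(self, levels_by_day, pos, cov=20):
        return {
            d: make_calls([("chr1", p, round(l * cov), cov) for p, l in zip(pos, levels)])
            for d, levels in levels_by_day.items()
        }

    def test_identical_clones_have_zero_sd(self):
        pos = [10, 30, 50, 70]
        series = self._series({0: [0.1] * 4, 3: [0.5] * 4}, pos)
        out = gain_curve({"c1": series, "c2": series}, [GenomicInterval("chr1", 0, 200)])
        assert np.allclose(out["sd"], 0.0)

    def test_common_cpg_set_shared_across_days(self):
        pos = [10, 30, 50, 70]
        series = self._series({0: [0.1] * 4, 3: [0.5] * 4}, pos)
        # drop one dyad's coverage on day 3 only: it must leave every day
        series[3].loc[0, "n_total"] = 2
        out = gain_curve({"c1": series}, [GenomicInterval("chr1", 0, 200)])
        assert (out["n_cpgs"] == 3).all()

    def test_day0_only_single_point(self):
        pos = [10, 30, 50, 70, 90]
        series = self._series({0: [0.2] * 5}, pos)
        out = gain_curve({"c1": series}, [GenomicInterval("chr1", 0, 200)])
        assert len(out) == 1 and out["day"].iloc[0] == 0

    def test_empty_common_set_is_error(self):
        pos = [10, 30]
        series = self._series({0: [0.1, 0.2]}, pos)
        with pytest.raises(ValueError, match="no CpGs"):
            gain_curve({"c1": series}, [GenomicInterval("chr2", 0, 200)])


class TestCgiClassSummary:
    def test_boundary_rules(self):
        # WT mean 0.81 -> hyper (strict >); WT mean 0.20 -> hypo (inclusive <=)
        cgis = [
            GenomicInterval("chr1", 0, 100, name="hi"),
            GenomicInterval("chr1", 200, 300, name="lo"),
        ]
        wt = make_calls(
            [("chr1", 10, 81, 100), ("chr1", 20, 81, 100), ("chr1", 30, 81, 100),
             ("chr1", 210, 20, 100), ("chr1", 220, 20, 100)]
        )
        out = cgi_class_summary(wt, wt, cgis)
        per = out.attrs["per_cgi"].set_index("name")
        assert per.loc["hi", "class"] == "hyper"
        assert per.loc["lo", "class"] == "hypo"

    def test_sample_equal_to_wt_reproduces_class_means(self):
        cgis = [GenomicInterval("chr1", 0, 100, name="a")]
        wt = make_calls([("chr1", 10, 5, 100), ("chr1", 20, 10, 100), ("chr1", 30, 15, 100)])
        out = cgi_class_summary(wt, wt, cgis)
        assert out["wt_mean"].iloc[0] == pytest.approx(out["sample_mean"].iloc[0])


class TestCgiK4Score:
    def test_all_equal_densities_score_100(self):
        ivs = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(20)]
        scores = cgi_k4_score(ivs, [10] * 20)
        assert np.allclose(scores, 100.0)

    def test_nearest_rank_top_percent_scaling(self):
        # densities 1..100 plus 49.5; nearest-rank 99th percentile = 99
        ivs = [GenomicInterval("chr1", i * 10, i * 10 + 2) for i in range(101)]
        counts = [2 * d for d in range(1, 101)] + [99]  # length-2 intervals
        scores = cgi_k4_score(ivs, counts)
        assert scores[-1] == pytest.approx(100 * 49.5 / 99) == pytest.approx(50.0)
        assert scores[98] == pytest.approx(100.0)  # density 99 = the quantile

    def test_values_above_quantile_capped_at_100(self):
        ivs = [GenomicInterval("chr1", i * 10, i * 10 + 1) for i in range(101)]
        scores = cgi_k4_score(ivs, list(range(1, 101)) + [1000])
        assert scores.max() == 100.0
        assert ((scores >= 0) & (scores <= 100)).all()

    def test_all_zero_counts_score_zero(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        assert np.allclose(cgi_k4_score(ivs, [0, 0]), 0.0)

    def test_monotone_in_density(self):
        rng = np.random.default_rng(3)
        ivs = [GenomicInterval("chr1", i * 10, i * 10 + 4) for i in range(50)]
        counts = rng.integers(0, 200, 50)
        scores = cgi_k4_score(ivs, counts)
        order = np.argsort(counts)  # equal lengths: density order = count order
        assert (np.diff(scores[order]) >= -1e-12).all()


class TestDeltaHistogram:
    def test_identical_samples_mass_in_zero_bin(self):
        calls = make_calls([("chr1", i * 50 + 5, 3, 10) for i in range(60)])
        hist = delta_histogram(calls, calls)
        nonzero = hist[hist["count"] > 0]
        assert len(nonzero) == 1
        assert nonzero["bin_left"].iloc[0] <= 0 < nonzero["bin_right"].iloc[0]

    def test_uniform_shift_lands_in_expected_edge_bins(self):
        a = make_calls([("chr1", i * 50 + 5, 2, 10) for i in range(60)])
        b = make_calls([("chr1", i * 50 + 5, 5, 10) for i in range(60)])
        hist = delta_histogram(a, b)
        nonzero = hist[hist["count"] > 0]
        assert len(nonzero) == 1
        left = nonzero["bin_left"].iloc[0]
        assert left in (0.25, 0.30)

    def test_no_qualifying_tiles_empty_histogram(self, caplog):
        a = make_calls([("chr1", 5, 2, 10)])
        with caplog.at_level("WARNING"):
            hist = delta_histogram(a, a)
        assert hist["count"].sum() == 0


class TestContextSummary:
    def test_reports_na_for_missing_context(self):
        cg = make_calls([("chr1", 10, 5, 10)])
        out = context_summary({"CG": cg}).set_index("context")
        assert np.isnan(out.loc["CA", "mean"])
        assert out.loc["CG", "mean"] == pytest.approx(0.5)
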