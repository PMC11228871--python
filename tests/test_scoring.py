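"""NG/NGR scoring: plate normalization, replicate aggregation, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coldscreen import (
    AnalysisError,
    GeneScore,
    PlateNormalizationError,
    PlantedEffect,
    SimConfig,
    aggregate_replicates,
    compute_ngr,
    normalize_plate,
    read_scores,
    score_screen,
    simulate_screen,
    summarize_distribution,
    write_scores,
)
from coldscreen.scoring import FLAG_LOW_REPLICATES, FLAG_MISSING_REF, FLAG_ZERO_SIZE


class TestNormalizePlate:
    @pytest.mark.parametrize("sizes, expected", [
        ([10, 20, 30], [0.5, 1.0, 1.5]),
        ([7.3, 7.3, 7.3, 7.3], [1.0, 1.0, 1.0, 1.0]),
        # even count: median is the mean of 6 and 10 -> 8
        ([4, 6, 10, 100], [0.5, 0.75, 1.25, 12.5]),
    ])
    def test_hand_computed_examples(self, sizes, expected):
        assert normalize_plate(sizes) == pytest.approx(expected, rel=1e-12)

    def test_median_of_returned_ng_is_one(self):
        rng = np.random.default_rng(11)
        odd = rng.lognormal(5, 0.4, 101)
        assert np.median(normalize_plate(odd)) == 1.0  # exact for odd counts
        even = rng.lognormal(5, 0.4, 100)
        assert np.median(normalize_plate(even)) == pytest.approx(1.0, rel=1e-9)

    def test_missing_colonies_propagate(self):
        ng = normalize_plate([10.0, np.nan, 30.0, 20.0])
        assert np.isnan(ng[1]) and np.isfinite(ng[[0, 2, 3]]).all()

    def test_unnormalizable_plates_error(self):
        with pytest.raises(PlateNormalizationError):
            normalize_plate([np.nan, np.nan])
        with pytest.raises(PlateNormalizationError):
            normalize_plate([0.0, 0.0, 0.0])

    def test_scale_invariance_within_4_ulp(self):
        rng = np.random.default_rng(5)
        sizes = rng.lognormal(5, 0.5, 500)
        ng = normalize_plate(sizes)
        for k in rng.lognormal(0, 2, 20):
            scaled = normalize_plate(sizes * k)
            assert np.all(np.abs(scaled - ng) <= 4 * np.spacing(np.abs(ng)))


class TestAggregateReplicates:
    def test_median_rule(self):
        assert aggregate_replicates([0.8, 1.0, 1.2])[0] == 1.0
        assert aggregate_replicates([0.5, 1.5])[0] == 1.0  # even-count median

    def test_low_replicates_flagged(self):
        ng, n, flags = aggregate_replicates([0.7], min_replicates=2)
        assert (ng, n) == (0.7, 1)
        assert FLAG_LOW_REPLICATES in flags

    def test_no_replicates_errors(self):
        with pytest.raises(AnalysisError):
            aggregate_replicates([np.nan])


class TestComputeNgr:
    @pytest.mark.parametrize("ng30, ng19, ngr, log2_ngr", [
        (1.0, 0.5, 0.5, -1.0),
        (0.73, 0.73, 1.0, 0.0),
        (0.3, 1.2, 4.0, 2.0),
    ])
    def test_ratio_and_log2(self, ng30, ng19, ngr, log2_ngr):
        score = compute_ngr(GeneScore("g", ng_30=ng30, ng_19=ng19))
        assert score.ngr == pytest.approx(ngr, rel=1e-12)
        assert score.log2_ngr == pytest.approx(log2_ngr, abs=1e-12)
        assert score.log2_ng_30 == pytest.approx(np.log2(ng30), rel=1e-12)

    def test_zero_reference_flags_and_voids_ngr(self):
        score = compute_ngr(GeneScore("g", ng_30=0.0, ng_19=0.5))
        assert score.ngr is None
        assert FLAG_ZERO_SIZE in score.qc_flags

    def test_missing_reference_flagged(self):
        score = compute_ngr(GeneScore("g", ng_30=None, ng_19=0.5))
        assert score.ngr is None
        assert FLAG_MISSING_REF in score.qc_flags


class TestSummarizeDistribution:
    def test_textbook_cases(self):
        s = summarize_distribution([-1, 0, 1], "log2_ngr")
        assert (s.median, s.sd, s.n) == (0.0, 1.0, 3)
        s = summarize_distribution([2.5] * 4, "log2_ngr")
        assert (s.median, s.sd) == (2.5, 0.0)

    def test_nonfinite_excluded_and_counted(self):
        s = summarize_distribution([1.0, np.nan, -np.inf, 2.0], "log2_ngr")
        assert s.n == 2 and s.n_nonfinite == 2

    def test_too_few_values_errors(self):
        with pytest.raises(AnalysisError):
            summarize_distribution([1.0], "log2_ngr")

    def test_monte_carlo_recovers_generator_parameters(self):
        draws = np.random.default_rng(2024).normal(0.0, 0.52, 10_001)
        s = summarize_distribution(draws, "log2_ngr")
        assert abs(s.median) < 0.02
        assert abs(s.sd - 0.52) < 0.02


class TestScoreScreen:
    def hand_table(self):
        # gene A: sizes 10/20/30 on plates whose medians are forced to 20
        rows = []
        for rep, (sa, sb) in enumerate([(10, 30), (20, 20), (30, 10)], start=1):
            for temp in ("30C", "19C"):
                factor = 2.0 if temp == "19C" else 1.0
                rows += [
                    (f"p-{temp}-{rep}", temp, rep, 1, 1, "geneA", sa * factor),
                    (f"p-{temp}-{rep}", temp, rep, 1, 2, "geneB", sb * factor),
                    (f"p-{temp}-{rep}", temp, rep, 1, 3, "geneC", 20 * factor),
                ]
        return pd.DataFrame(rows, columns=[
            "plate_id", "temperature", "replicate", "row", "col", "gene_id", "size"])

    def test_matches_scalar_operations(self):
        scores = score_screen(self.hand_table(), query_label="q")
        # per-plate median is 20*factor; geneA NGs are {0.5, 1.0, 1.5} -> median 1
        assert scores.loc["geneA", "ng_30"] == 1.0
        assert scores.loc["geneA", "ng_19"] == 1.0
        assert scores.loc["geneC", "ngr"] == 1.0
        assert (scores["n_rep_30"] == 3).all()

    def test_log2_fields_consistent(self):
        sim = simulate_screen(SimConfig(n_genes=300, seed=9), "q")
        scores = score_screen(sim.colonies, query_label="q")
        ok = scores.dropna(subset=["ngr"])
        assert np.allclose(ok["log2_ngr"], np.log2(ok["ngr"]), rtol=1e-12)
        assert np.allclose(ok["log2_ng_30"], np.log2(ok["ng_30"]), rtol=1e-12)

    def test_ranking_by_ngr_equals_ranking_by_log2_ngr(self):
        sim = simulate_screen(SimConfig(n_genes=300, seed=10), "q")
        scores = score_screen(sim.colonies, query_label="q").dropna(subset=["ngr"])
        assert (scores["ngr"].rank() == scores["log2_ngr"].rank()).all()

    def test_noise_free_planted_ngr_exact(self):
        planted = PlantedEffect("gene_0007", 0.25, 4.0, "cs_suppressor")
        cfg = SimConfig(n_genes=200, seed=1, baseline_log_size_sd=0.0,
                        colony_noise_sd=0.0, dropout_prob=0.0,
                        planted_effects=(planted,))
        scores = score_screen(simulate_screen(cfg, "q").colonies, query_label="q")
        assert scores.loc["gene_0007", "ngr"] == 4.0 / 0.25  # exact
        neutral = scores.drop("gene_0007")
        assert (neutral["ngr"] == 1.0).all()

    def test_plate_effects_removed_by_normalization(self):
        # Variance of log2 NG with plate effects on is indistinguishable
        # from the colony-noise-only simulation (F-test, alpha=0.01).
        rejections = 0
        for seed in range(20):
            out = {}
            for sd in (0.0, 0.4):
                cfg = SimConfig(n_genes=500, seed=seed, plate_effect_sd=sd,
                                dropout_prob=0.0, baseline_log_size_sd=0.0)
                scores = score_screen(simulate_screen(cfg, f"pe{sd}").colonies)
                out[sd] = scores["log2_ng_30"].to_numpy()
            f = np.var(out[0.4], ddof=1) / np.var(out[0.0], ddof=1)
            dof = len(out[0.4]) - 1
            p = 2 * min(stats.f.sf(f, dof, dof), stats.f.cdf(f, dof, dof))
            rejections += p < 0.01
        assert rejections <= 2  # expected 0.2 under the null

    def test_dead_at_cold_gene_scores_zero_ngr(self):
        table = self.hand_table()
        table.loc[(table["gene_id"] == "geneB") & (table["temperature"] == "19C"), "size"] = 0.0
        scores = score_screen(table)
        assert scores.loc["geneB", "ngr"] == 0.0
        assert scores.loc["geneB", "log2_ngr"] == -np.inf

    def test_score_table_round_trip(self, tmp_path):
        sim = simulate_screen(SimConfig(n_genes=50, seed=2), "q")
        scores = score_screen(sim.colonies, query_label="q")
        path = tmp_path / "scores.tsv"
        write_scores(scores, path)
        out = read_scores(path)
        pd.testing.assert_frame_equal(out, scores, check_dtype=False)
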