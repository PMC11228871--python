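"""Multi-screen comparison: filtering, suppressors, reverters, Venn regions."""

import numpy as np
import pytest

from coldscreen import (
    AnalysisError,
    HitCall,
    PlantedEffect,
    SimConfig,
    classify_reverters,
    classify_suppressors,
    filter_query_specific,
    score_screen,
    simulate_parallel_screens,
    simulate_screen,
    venn_partition,
)
from conftest import make_scores


def hit(gene, value, direction, statistic="log2_ng_30", query="taz1"):
    return HitCall(gene, query, statistic, value, direction, "two_sd", 0.0)


class TestFilterQuerySpecific:
    def test_similar_interaction_removed(self):
        hits = [hit("gA", -2.0, "negative")]
        other = make_scores({"gA": -1.8}, statistic="log2_ng_30", query_label="rif1")
        kept, excluded = filter_query_specific(hits, other)
        assert kept == []
        assert excluded[0][0] == "gA"

    def test_dissimilar_interaction_retained(self):
        hits = [hit("gA", -2.0, "negative")]
        other = make_scores({"gA": 0.1}, statistic="log2_ng_30")
        kept, excluded = filter_query_specific(hits, other)
        assert [h.gene_id for h in kept] == ["gA"] and excluded == []

    def test_same_direction_hit_in_other_screen_removed(self):
        hits = [hit("gA", -2.0, "negative")]
        other = make_scores({"gA": -0.3}, statistic="log2_ng_30")
        other_hits = [hit("gA", -0.3, "negative", query="rif1")]
        kept, excluded = filter_query_specific(hits, other, other_hits)
        assert kept == [] and "hit" in excluded[0][1]

    def test_statistic_mismatch_errors(self):
        hits = [hit("gA", -2.0, "negative", statistic="log2_ngr")]
        other = make_scores({"gA": -1.8}, statistic="log2_ng_30").drop(columns=["log2_ngr"])
        with pytest.raises(AnalysisError, match="not scored"):
            filter_query_specific(hits, other)

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            genes = [f"g{i}" for i in range(n)]
            primary_vals = rng.normal(0, 2, n)
            other_vals = rng.normal(0, 2, n)
            direction = "negative" if rng.random() < 0.5 else "positive"
            sign = -1 if direction == "negative" else 1
            hits = [hit(g, v, direction) for g, v in zip(genes, primary_vals)
                    if sign * v > 1]
            other = make_scores(dict(zip(genes, other_vals)), statistic="log2_ng_30")
            kept, _ = filter_query_specific(hits, other, similarity_fraction=0.5)
            expected = {
                h.gene_id for h in hits
                if not (np.sign(other_vals[genes.index(h.gene_id)]) == sign
                        and abs(other_vals[genes.index(h.gene_id)]) >= 0.5 * abs(h.value))
            }
            assert {h.gene_id for h in kept} == expected


class TestClassifySuppressors:
    def noise_free_scores(self, planted):
        cfg = SimConfig(n_genes=80, seed=1, baseline_log_size_sd=0.0,
                        colony_noise_sd=0.0, dropout_prob=0.0,
                        planted_effects=planted)
        return score_screen(simulate_screen(cfg, "taz1").colonies, query_label="taz1")

    def test_planted_suppressor_recovered(self):
        planted = (PlantedEffect("gene_0009", 1.0, 4.0, "cs_suppressor"),)
        suppressors, hits = classify_suppressors(self.noise_free_scores(planted),
                                                 method="two_sd")
        assert suppressors == {"gene_0009"}
        assert hits[0].statistic_name == "log2_ngr" and hits[0].direction == "positive"

    def test_shared_sickness_is_not_a_suppressor(self):
        # sick at both temperatures: the NGR ratio cancels the effect
        planted = (PlantedEffect("gene_0009", 0.25, 0.25, "synthetic_sick"),
                   PlantedEffect("gene_0011", 1.0, 4.0, "cs_suppressor"))
        suppressors, _ = classify_suppressors(self.noise_free_scores(planted),
                                              method="two_sd")
        assert "gene_0009" not in suppressors


class TestClassifyReverters:
    def build_screens(self, plant):
        """Four score frames over 100 genes with N(0, 0.4) noise; ``plant``
        maps screen -> {gene: log2 ngr value}."""
        rng = np.random.default_rng(12)
        genes = [f"g{i:03d}" for i in range(100)]
        frames = {}
        for name in ("taz1rif1", "taz1Srif1", "rif1", "Srif1"):
            values = dict(zip(genes, rng.normal(0, 0.4, 100)))
            values.update(plant.get(name, {}))
            frames[name] = make_scores(values, query_label=name)
        return frames

    def test_planted_reverter_classified(self):
        frames = self.build_screens({
            "taz1rif1": {"g000": -3.0}, "taz1Srif1": {"g000": -3.0},
            "rif1": {"g000": 0.05}, "Srif1": {"g000": -0.1},
        })
        reverters, evidence = classify_reverters(
            frames["taz1rif1"], frames["taz1Srif1"], frames["rif1"], frames["Srif1"])
        assert "g000" in reverters
        assert evidence.loc[evidence["gene_id"] == "g000", "status"].iloc[0] == "reverter"

    def test_sick_in_single_mutant_excluded(self):
        frames = self.build_screens({
            "taz1rif1": {"g000": -3.0}, "taz1Srif1": {"g000": -3.0},
            "rif1": {"g000": -3.0}, "Srif1": {"g000": 0.0},
        })
        reverters, evidence = classify_reverters(
            frames["taz1rif1"], frames["taz1Srif1"], frames["rif1"], frames["Srif1"])
        assert "g000" not in reverters
        reason = evidence.loc[evidence["gene_id"] == "g000", "reasons"].iloc[0]
        assert "single mutant rif1" in reason

    def test_hit_in_only_one_double_screen_excluded(self):
        frames = self.build_screens({
            "taz1rif1": {"g000": -3.0}, "taz1Srif1": {"g000": 0.0},
            "rif1": {"g000": 0.0}, "Srif1": {"g000": 0.0},
        })
        reverters, evidence = classify_reverters(
            frames["taz1rif1"], frames["taz1Srif1"], frames["rif1"], frames["Srif1"])
        assert "g000" not in reverters
        reason = evidence.loc[evidence["gene_id"] == "g000", "reasons"].iloc[0]
        assert "taz1Srif1" in reason

    def test_missing_single_screen_value_is_unclassifiable(self):
        frames = self.build_screens({
            "taz1rif1": {"g000": -3.0}, "taz1Srif1": {"g000": -3.0},
            "rif1": {"g000": np.nan}, "Srif1": {"g000": 0.0},
        })
        reverters, evidence = classify_reverters(
            frames["taz1rif1"], frames["taz1Srif1"], frames["rif1"], frames["Srif1"])
        assert "g000" not in reverters
        assert evidence.loc[evidence["gene_id"] == "g000", "status"].iloc[0] == "unclassifiable"

    def test_missing_screen_errors(self):
        frames = self.build_screens({})
        with pytest.raises(AnalysisError, match="missing screen"):
            classify_reverters(frames["taz1rif1"], frames["taz1Srif1"],
                               frames["rif1"].iloc[0:0], frames["Srif1"])

    def test_monotone_in_single_mutant_tolerance(self):
        frames = self.build_screens({
            "taz1rif1": {f"g{i:03d}": -3.0 for i in range(10)},
            "taz1Srif1": {f"g{i:03d}": -3.0 for i in range(10)},
        })
        args = (frames["taz1rif1"], frames["taz1Srif1"], frames["rif1"], frames["Srif1"])
        small, _ = classify_reverters(*args, single_mutant_tolerance_sd=0.5)
        large, _ = classify_reverters(*args, single_mutant_tolerance_sd=1.5)
        assert small <= large

    def test_permutation_invariance(self):
        frames = self.build_screens({
            "taz1rif1": {"g000": -3.0, "g001": -3.0},
            "taz1Srif1": {"g000": -3.0, "g001": -3.0},
        })
        ref, _ = classify_reverters(frames["taz1rif1"], frames["taz1Srif1"],
                                    frames["rif1"], frames["Srif1"])
        shuffled = {k: v.sample(frac=1, random_state=5) for k, v in frames.items()}
        perm, _ = classify_reverters(shuffled["taz1rif1"], shuffled["taz1Srif1"],
                                     shuffled["rif1"], shuffled["Srif1"])
        assert ref == perm

    def test_end_to_end_construction_oracle(self):
        # a gene neutral in the singles but deleterious in the cold in both
        # double-query screens must come out a reverter (noise-free)
        base = SimConfig(n_genes=60, seed=2, baseline_log_size_sd=0.0,
                         colony_noise_sd=0.0, dropout_prob=0.0)
        sick = [PlantedEffect("gene_0021", 1.0, 0.2, "reverter")]
        sims = simulate_parallel_screens(base, {
            "taz1rif1": sick, "taz1Srif1": sick, "rif1": [], "Srif1": [],
        })
        scores = {q: score_screen(s.colonies, query_label=q) for q, s in sims.items()}
        reverters, _ = classify_reverters(scores["taz1rif1"], scores["taz1Srif1"],
                                          scores["rif1"], scores["Srif1"])
        assert "gene_0021" in reverters


class TestVennPartition:
    def test_two_set_example(self):
        venn = venn_partition({"A": {"a", "b"}, "B": {"b", "c"}})
        assert venn.region("A") == {"a"}
        assert venn.region("A", "B") == {"b"}
        assert venn.region("B") == {"c"}

    def test_identical_sets_single_region(self):
        venn = venn_partition({"A": {"x", "y"}, "B": {"x", "y"}})
        assert dict(venn.regions) == {frozenset({"A", "B"}): frozenset({"x", "y"})}

    def test_too_few_sets_errors(self):
        with pytest.raises(AnalysisError):
            venn_partition({"A": {"a"}})

    def test_random_three_sets_match_membership_counting(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(100)]
        sets = {lbl: {g for g in genes if rng.random() < 0.4} for lbl in "ABC"}
        venn = venn_partition(sets)
        # brute force: classify every gene by its membership vector
        expected = {}
        for g in set().union(*sets.values()):
            key = frozenset(lbl for lbl in sets if g in sets[lbl])
            expected.setdefault(key, set()).add(g)
        assert {k: set(v) for k, v in venn.regions.items()} == expected
        # regions partition the union
        union = set().union(*sets.values())
        assert sum(len(v) for v in venn.regions.values()) == len(union)
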