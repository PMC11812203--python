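"""Permutation nulls, recovery curves, ToD optimisation, ROC/PR,
ranking, enrichment and the train/test machinery."""

import numpy as np
import pandas as pd
import pytest

from slcscout import (
    bootstrap_stat,
    make_known_pairs,
    optimize_tod,
    partition_pairs,
    pathway_enrichment,
    rank_predictions,
    recovery_curve,
    roc_pr,
    simulate_random_pairs,
    train_test_cycle,
)
from slcscout.evaluation import TrainTestSettings, fractional_difference
from conftest import hypergeom_oracle, mann_whitney_auc_oracle


class TestSimulateRandomPairs:
    def test_never_reproduces_known_rows(self):
        known = make_known_pairs([("S1", "M1"), ("S2", "M2")])
        tables = simulate_random_pairs(known, ["M1", "M2", "M3"], n=50, seed=0)
        for t in tables:
            keys = set(zip(t["slc_id"], t["target_id"]))
            assert ("S1", "M1") not in keys and ("S2", "M2") not in keys

    def test_deterministic_under_seed(self):
        known = make_known_pairs([("S1", "M1"), ("S2", "M2")])
        a = simulate_random_pairs(known, ["M1", "M2", "M3"], n=5, seed=7)
        b = simulate_random_pairs(known, ["M1", "M2", "M3"], n=5, seed=7)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_shapes_preserved(self):
        known = make_known_pairs([(f"S{i}", f"M{i}") for i in range(40)])
        universe = [f"M{i}" for i in range(60)]
        tables = simulate_random_pairs(known, universe, n=100, seed=1)
        assert len(tables) == 100
        assert all(len(t) == 40 for t in tables)
        assert all((t["slc_id"] == known["slc_id"]).all() for t in tables)


class TestRecoveryCurve:
    def test_strictly_greater_rule(self):
        out = recovery_curve([5, 20, 50])
        assert out.loc[out["cutoff"] == 10, "fraction"].iloc[0] == pytest.approx(2 / 3)
        assert out.loc[out["cutoff"] == 20, "fraction"].iloc[0] == pytest.approx(1 / 3)

    def test_all_zero_scores(self):
        assert (recovery_curve([0, 0, 0])["fraction"] == 0).all()

    def test_scores_above_grid(self):
        assert (recovery_curve([101, 200])["fraction"] == 1).all()

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(2)
        frac = recovery_curve(rng.uniform(0, 120, size=200))["fraction"].to_numpy()
        assert (np.diff(frac) <= 1e-12).all()


class TestOptimizeTod:
    def test_no_signal_objective_near_zero(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=200).tolist()
        rand_sets = [rng.permutation(vals).tolist() for _ in range(10)]
        best, diag = optimize_tod(vals, rand_sets, [0.0, 0.5, 1.0])
        assert np.all(np.abs(diag["objective"]) < 0.02)

    def test_shifted_known_set_prefers_separating_tod(self):
        rng = np.random.default_rng(4)
        known = (rng.normal(size=100) + 2.0).tolist()
        rand_sets = [rng.normal(size=100).tolist() for _ in range(10)]
        best, diag = optimize_tod(known, rand_sets, [-1.0, 0.0, 0.5, 1.0, 1.5])
        assert diag["objective"].max() > 0.05
        assert best >= 0.0

    def test_single_candidate_returned(self):
        vals = list(range(20))
        best, _ = optimize_tod(vals, [vals], [0.25])
        assert best == 0.25

    def test_tie_breaks_toward_smaller(self):
        vals = [float(v) for v in range(11)]
        # identical known and random: every candidate ties at objective 0
        best, _ = optimize_tod(vals, [vals], [0.0, 1.0, 2.0])
        assert best == 0.0


class TestBootstrap:
    def test_constant_values(self):
        out = bootstrap_stat([4.0] * 10, B=100, seed=0)
        assert np.allclose(out, 4.0) and len(out) == 100

    def test_deterministic(self):
        v = list(range(30))
        assert np.array_equal(
            bootstrap_stat(v, B=50, seed=9), bootstrap_stat(v, B=50, seed=9)
        )


class TestRocPr:
    def test_perfect_separation(self):
        roc, pr = roc_pr([0.9, 0.8], [0.1, 0.2])
        assert roc == pytest.approx(1.0) and pr == pytest.approx(1.0)

    def test_identical_distributions(self):
        roc, _ = roc_pr([1, 2, 3], [1, 2, 3])
        assert roc == pytest.approx(0.5)

    def test_interleaved_example(self):
        roc, _ = roc_pr([2], [1, 3])
        assert roc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_roc_equals_normalized_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, 9))
        n_neg = int(rng.integers(1, 9))
        pos = rng.integers(0, 6, size=n_pos).astype(float)
        neg = rng.integers(0, 6, size=n_neg).astype(float)
        roc, _ = roc_pr(pos, neg)
        assert roc == pytest.approx(mann_whitney_auc_oracle(pos, neg))


class TestRankPredictions:
    def _conf(self, rows):
        return pd.DataFrame(rows, columns=["slc_id", "metabolite_id", "confidence"])

    def test_zero_scores_excluded(self):
        out = rank_predictions(
            self._conf([("S", "a", 10.0), ("S", "b", 5.0), ("S", "c", 0.0)])
        )
        assert len(out) == 2
        assert out.set_index("metabolite_id")["rank_percentile"].to_dict() == {
            "a": 0.5, "b": 1.0,
        }

    def test_ties_share_mean_rank(self):
        out = rank_predictions(
            self._conf([("S", m, v) for m, v in [("a", 9), ("b", 9), ("c", 4), ("d", 2)]])
        )
        idx = out.set_index("metabolite_id")
        assert idx.loc["a", "rank"] == 1.5 and idx.loc["b", "rank"] == 1.5

    def test_top_four_percent_filter(self):
        rows = [("S", f"m{i}", 100.0 - i) for i in range(100)]
        out = rank_predictions(self._conf(rows))
        assert (out["rank_percentile"] <= 0.04).sum() == 4


class TestPathwayEnrichment:
    def _pathways(self, mapping):
        rows = [
            {"pathway_id": pw, "metabolite_id": m}
            for pw, mets in mapping.items() for m in mets
        ]
        return pd.DataFrame(rows)

    def test_exact_hypergeometric_example(self):
        universe = [f"m{i}" for i in range(10)]
        pw = self._pathways({"P": universe[:5]})
        out = pathway_enrichment(universe[:4], pw, universe)
        # all 4 selected inside a 5-member pathway of a 10-member universe
        assert out["p"].iloc[0] == pytest.approx(5 / 210)
        assert out["p"].iloc[0] == pytest.approx(hypergeom_oracle(4, 10, 5, 4))

    def test_disjoint_pathway_p_one(self):
        universe = [f"m{i}" for i in range(10)]
        pw = self._pathways({"P": universe[5:]})
        out = pathway_enrichment(universe[:3], pw, universe)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_selected_equals_universe(self):
        universe = [f"m{i}" for i in range(8)]
        pw = self._pathways({"P": universe[:4]})
        out = pathway_enrichment(universe, pw, universe)
        assert out["overlap"].iloc[0] == 4 and out["p"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"m{i}" for i in range(12)]
        members = list(rng.choice(universe, size=5, replace=False))
        selected = list(rng.choice(universe, size=4, replace=False))
        out = pathway_enrichment(selected, self._pathways({"P": members}), universe)
        k = len(set(members) & set(selected))
        assert out["p"].iloc[0] == pytest.approx(hypergeom_oracle(k, 12, 5, 4))

    def test_empty_selection_rejected(self):
        with pytest.raises(Exception, match="empty"):
            pathway_enrichment([], self._pathways({"P": ["a"]}), ["a"])


class TestTrainTest:
    def test_partition_sizes_667(self):
        known = make_known_pairs([(f"S{i}", f"M{i}") for i in range(667)])
        train, test = partition_pairs(known, split=0.7, rng=0)
        assert (len(train), len(test)) == (466, 201)

    def test_partition_deterministic(self):
        known = make_known_pairs([(f"S{i}", f"M{i}") for i in range(50)])
        t1, _ = partition_pairs(known, rng=np.random.default_rng(5))
        t2, _ = partition_pairs(known, rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(t1, t2)

    def test_cycle_on_synthetic_panel(self):
        from slcscout import SynthConfig, run_scoring_pipeline, synth_panel

        panel = synth_panel(
            SynthConfig(seed=11, n_planted_pairs=25, derivative_branches=1,
                        n_cell_lines=120)
        )
        result = run_scoring_pipeline(panel)
        universe = sorted(result.confidence["metabolite_id"].unique())
        settings = TrainTestSettings(iters=2, n_random_tables=5, tod_grid=(0.0, 1.0))
        metrics = train_test_cycle(
            result.correlations, result.dependency, result.adjacency,
            panel.known_pairs, universe, result.params, settings, seed=3,
        )
        assert len(metrics) == 2
        assert (metrics["n_train"] == 17).all() and (metrics["n_test"] == 8).all()
        assert metrics["roc_auc"].between(0, 1).all()
        # planted signal should separate test pairs from random pairs
        assert (metrics["mean_test_score"] > metrics["mean_random_score"]).all()

    def test_fractional_difference_zero_for_identical(self):
        vals = [10.0, 30.0, 70.0]
        assert fractional_difference(vals, [vals, vals]) == pytest.approx(0.0)
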