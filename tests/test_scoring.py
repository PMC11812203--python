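"""Decile sub-scores, the adjacency piecewise rule and the weighted
confidence combination, anchored on the fully worked demo example."""

import numpy as np
import pytest

from slcscout import (
    ScoreParams,
    ValidationError,
    adjacency_subscore,
    confidence_scores,
    default_params,
    known_quantiles,
    subscore,
)
from slcscout.demo import PANEL_KNOTS, demo_inputs, demo_scores


class TestKnownQuantiles:
    def test_integer_decile_knots(self):
        q = known_quantiles(range(11), tod=0.0)
        assert np.allclose(q, np.arange(11))

    def test_all_equal_values(self):
        q = known_quantiles([2.0] * 11, tod=1.0)
        assert q[0] == 1.0 and np.allclose(q[1:], 2.0)

    def test_tod_above_max_rejected(self):
        with pytest.raises(ValidationError, match="at or above ToD"):
            known_quantiles(range(11), tod=99.0)

    def test_tod_inside_distribution_filters_below(self):
        # deciles come from the known values at or above ToD
        q = known_quantiles(list(range(21)), tod=10.0)
        assert q[0] == 10.0
        assert np.allclose(q[1:], np.arange(11, 21))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError, match=">=11"):
            known_quantiles(range(10), tod=0.0)


class TestSubscore:
    @pytest.fixture
    def knots(self):
        return known_quantiles(PANEL_KNOTS["CCLE2019"], tod=0.0)

    def test_sixth_decile_interval(self, knots):
        # 0.96 sits in [50%, 60%) of the known distribution
        assert subscore(0.96, 0.0, knots) == 6

    def test_below_tod_scores_zero(self, knots):
        assert subscore(-0.97, 0.0, knots) == 0

    def test_top_knot_capped_at_eleven(self, knots):
        assert subscore(knots[10], 0.0, knots) == 11
        assert subscore(knots[10] + 100.0, 0.0, knots) == 11

    def test_tod_boundary_scores_one(self, knots):
        assert subscore(0.0, 0.0, knots) == 1

    def test_missing_scores_zero(self, knots):
        assert subscore(float("nan"), 0.0, knots) == 0

    def test_monotone_in_value(self, knots):
        rng = np.random.default_rng(0)
        vals = np.sort(rng.uniform(-1.5, 2.5, size=60))
        scores = [subscore(v, 0.0, knots) for v in vals]
        assert all(a <= b for a, b in zip(scores, scores[1:]))


class TestAdjacencySubscore:
    @pytest.fixture
    def ccl_knots(self):
        return known_quantiles(PANEL_KNOTS["CCL180"], tod=1.0)

    def test_half_point_band(self, ccl_knots):
        assert adjacency_subscore(0.5, 1.0, 0.2, ccl_knots) == 0.5

    def test_tenth_decile_interval(self, ccl_knots):
        assert adjacency_subscore(1.95, 1.0, 0.2, ccl_knots) == 10

    def test_below_floor_zero(self, ccl_knots):
        assert adjacency_subscore(0.1, 1.0, 0.2, ccl_knots) == 0.0

    def test_floor_above_tod_acts_as_hard_floor(self):
        # NCI60-style defaults: ToD'=0.1 above ToD=0.0
        knots = known_quantiles(PANEL_KNOTS["NCI60"], tod=0.0)
        assert adjacency_subscore(0.05, 0.0, 0.1, knots) == 0.0
        assert adjacency_subscore(1.5, 0.0, 0.1, knots) == 9


class TestConfidenceScores:
    def test_worked_example_components(self):
        sc = demo_scores()
        assert sc.cell_panel_score == 18
        assert sc.with_gene_dep == 26
        assert sc.adjacency_score == 46.5
        assert sc.confidence == 72.5

    def test_worked_example_subscores(self):
        row = demo_scores().row
        assert row["sub_NCI60"] == 0
        assert row["sub_CCLE2019"] == 6
        assert row["sub_CCL180"] == 0
        assert row["gene_dep_subscore"] == 8

    def test_all_below_threshold_scores_zero(self):
        inputs = demo_inputs()
        corr = inputs.correlations.copy()
        mask = corr["slc_id"] == "SLC35B1"
        corr.loc[mask, "rho_transformed"] = -5.0
        table = confidence_scores(
            corr, None, inputs.adjacency, inputs.known_pairs, inputs.params
        )
        row = table[(table["slc_id"] == "SLC35B1") & (table["metabolite_id"] == "glutamate")]
        assert row["confidence"].iloc[0] == 0.0

    def test_monotone_in_any_transformed_rho(self):
        inputs = demo_inputs()
        base = confidence_scores(
            inputs.correlations, inputs.dependency, inputs.adjacency,
            inputs.known_pairs, inputs.params,
        )
        base_val = base.set_index(["slc_id", "metabolite_id"]).loc[
            ("SLC35B1", "glutamate"), "confidence"
        ]
        bumped = inputs.correlations.copy()
        mask = (
            (bumped["slc_id"] == "SLC35B1")
            & (bumped["metabolite_id"] == "glutamate")
            & (bumped["dataset_id"] == "NCI60")
        )
        bumped.loc[mask, "rho_transformed"] = 1.7
        out = confidence_scores(
            bumped, inputs.dependency, inputs.adjacency,
            inputs.known_pairs, inputs.params,
        )
        new_val = out.set_index(["slc_id", "metabolite_id"]).loc[
            ("SLC35B1", "glutamate"), "confidence"
        ]
        assert new_val >= base_val

    def test_component_isolation(self):
        # with c=0 and a vanishing CRISPR cutoff, only panels contribute
        inputs = demo_inputs()
        params = ScoreParams(
            tod=inputs.params.tod, tod_prime=inputs.params.tod_prime,
            crispr_p_cutoff=1e-300, weight_a=3.0, weight_b=1.0, weight_c=0.0,
        )
        table = confidence_scores(
            inputs.correlations, inputs.dependency, inputs.adjacency,
            inputs.known_pairs, params,
        )
        datasets = list(PANEL_KNOTS)
        panel_sum = sum(table[f"sub_{ds}"] for ds in datasets)
        assert np.allclose(table["confidence"], 3.0 * panel_sum)

    def test_subscore_ranges(self):
        table = demo_scores().table
        for ds in PANEL_KNOTS:
            assert table[f"sub_{ds}"].between(0, 11).all()
        assert table["gene_dep_subscore"].between(0, 11).all()
        assert (table["adjacency_score"] >= 0).all()
        assert np.allclose(table["adjacency_score"] % 0.5, 0.0)

    def test_empty_known_set_rejected(self):
        inputs = demo_inputs()
        bad_known = inputs.known_pairs.copy()
        bad_known["target_id"] = "nonexistent"
        bad_known["slc_id"] = [f"X{i}" for i in range(len(bad_known))]
        with pytest.raises(ValidationError):
            confidence_scores(
                inputs.correlations, None, None, bad_known, inputs.params
            )


def test_default_params_match_published_table():
    p = default_params()
    assert p.tod == {"NCI60": 0.0, "CCLE2019": 0.0, "CCL180": 1.0}
    assert p.tod_prime == {"NCI60": 0.1, "CCLE2019": 0.1, "CCL180": 0.2}
    assert p.crispr_p_cutoff == 0.16
    assert (p.weight_a, p.weight_b, p.weight_c) == (3.0, 1.0, 1.0)
    assert p.adjacency_radius == 2
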