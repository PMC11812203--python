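"""Spearman panels, BH adjustment, the transformed-rho scale and
cross-panel concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slcscout import (
    OmicsMatrix,
    bh_adjust,
    correlate_panel,
    dataset_concordance,
    transform_rho,
)
from conftest import bh_oracle, spearman_oracle


def _pair_matrices(x, y):
    samples = [f"s{i}" for i in range(len(x))]
    expr = OmicsMatrix(
        pd.DataFrame([x], index=["SLC"], columns=samples), "pseudocounts"
    )
    metab = OmicsMatrix(
        pd.DataFrame([y], index=["M"], columns=samples), "metabolite_level"
    )
    return expr, metab


def _corr_table(rows):
    return pd.DataFrame(
        rows,
        columns=["slc_id", "metabolite_id", "dataset_id", "n_samples", "rho", "p"],
    )


class TestCorrelatePanel:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [1, 2, 3, 4, 5, 6, 7, 8, 9, 10], 1.0),
            ([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [10, 9, 8, 7, 6, 5, 4, 3, 2, 1], -1.0),
        ],
    )
    def test_perfect_monotone(self, x, y, expected):
        expr, metab = _pair_matrices(x, y)
        out = correlate_panel(expr, metab, ["SLC"], min_overlap=3)
        assert out["rho"].iloc[0] == pytest.approx(expected)

    def test_hand_formula_example(self):
        # d^2 = (0,1,1,0): rho = 1 - 6*2/(4*15) = 0.8
        expr, metab = _pair_matrices([1, 2, 3, 4], [1, 3, 2, 4])
        out = correlate_panel(expr, metab, ["SLC"], min_overlap=3)
        assert out["rho"].iloc[0] == pytest.approx(0.8)

    def test_constant_variable_flagged(self, caplog):
        expr, metab = _pair_matrices([1, 2, 3, 4], [5, 5, 5, 5])
        with caplog.at_level("WARNING"):
            out = correlate_panel(expr, metab, ["SLC"], min_overlap=3)
        assert len(out) == 1 and np.isnan(out["rho"].iloc[0])

    def test_min_overlap_drops_pair(self):
        x = [1.0, 2.0, 3.0, np.nan, np.nan, np.nan]
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        expr, metab = _pair_matrices(x, y)
        out = correlate_panel(expr, metab, ["SLC"], min_overlap=4)
        assert out.empty

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_brute_force_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        expr, metab = _pair_matrices(x, y)
        out = correlate_panel(expr, metab, ["SLC"], min_overlap=3)
        rho_scipy, p_scipy = stats.spearmanr(x, y)
        assert out["rho"].iloc[0] == pytest.approx(spearman_oracle(x, y))
        assert out["rho"].iloc[0] == pytest.approx(rho_scipy)
        assert out["p"].iloc[0] == pytest.approx(p_scipy, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        e1, m1 = _pair_matrices(x, y)
        e2, m2 = _pair_matrices(np.exp(x), y**3 + 5 * y)
        r1 = correlate_panel(e1, m1, ["SLC"], min_overlap=3)["rho"].iloc[0]
        r2 = correlate_panel(e2, m2, ["SLC"], min_overlap=3)["rho"].iloc[0]
        assert r1 == pytest.approx(r2)


class TestBHAdjust:
    def test_hand_example(self):
        rows = [("S", f"m{i}", "D", 10, 0.5, p) for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        out = bh_adjust(_corr_table(rows))
        assert np.allclose(out["p_adj"], 0.04)

    def test_single_row_family(self):
        out = bh_adjust(_corr_table([("S", "m", "D", 10, 0.5, 0.3)]))
        assert out["p_adj"].iloc[0] == pytest.approx(0.3)

    def test_p_of_one(self):
        out = bh_adjust(_corr_table([("S", "m", "D", 10, 0.5, 1.0), ("S", "m2", "D", 10, 0.5, 0.2)]))
        assert out.loc[out["metabolite_id"] == "m", "p_adj"].iloc[0] == 1.0

    @pytest.mark.parametrize("seed", [1, 5])
    def test_matches_oracle_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=12)
        rows = [("S", f"m{i}", "D", 10, 0.1, pi) for i, pi in enumerate(p)]
        out = bh_adjust(_corr_table(rows)).set_index("metabolite_id")
        expected = bh_oracle(p)
        for i in range(12):
            assert out.loc[f"m{i}", "p_adj"] == pytest.approx(expected[i])
        shuffled = _corr_table(rows).sample(frac=1, random_state=0)
        out2 = bh_adjust(shuffled).set_index("metabolite_id")
        pd.testing.assert_series_equal(
            out["p_adj"].sort_index(), out2["p_adj"].sort_index()
        )

    def test_never_decreases_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=20)
        rows = [("S", f"m{i}", "D", 10, 0.1, pi) for i, pi in enumerate(p)]
        out = bh_adjust(_corr_table(rows))
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestTransformRho:
    def _table(self, abs_rhos, dataset="D"):
        rows = [
            ("S%d" % i, "met", dataset, 10, r, 0.1) for i, r in enumerate(abs_rhos)
        ]
        return _corr_table(rows)

    def test_hand_example(self):
        # |rho| = {0.9, 0.5, 0.1}: mean 0.5, sample SD 0.4
        out, stats_df = transform_rho(self._table([0.9, 0.5, 0.1]))
        top = out.loc[out["rho"] == 0.9, "rho_transformed"].iloc[0]
        assert top == pytest.approx(1.0)
        assert stats_df["mean_abs_rho"].iloc[0] == pytest.approx(0.5)

    def test_value_at_mean_is_zero(self):
        out, _ = transform_rho(self._table([0.9, 0.5, 0.1]))
        assert out.loc[out["rho"] == 0.5, "rho_transformed"].iloc[0] == pytest.approx(0.0)

    def test_sign_discarded(self):
        out, _ = transform_rho(self._table([-0.9, 0.5, 0.1]))
        assert out.loc[out["rho"] == -0.9, "rho_transformed"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_group_missing(self, caplog):
        with caplog.at_level("WARNING"):
            out, _ = transform_rho(self._table([0.4, 0.4, 0.4]))
        assert out["rho_transformed"].isna().all()

    def test_standardised_within_group(self):
        rng = np.random.default_rng(9)
        out, _ = transform_rho(self._table(rng.uniform(0, 1, size=25)))
        z = out["rho_transformed"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestConcordance:
    def _table(self, rhos):
        rows = [("S", f"m{i}", "D", 10, r, 0.1) for i, r in enumerate(rhos)]
        return _corr_table(rows)

    def test_identity_and_negation(self):
        a = self._table([0.1, 0.5, -0.3, 0.8])
        rho, _, n = dataset_concordance(a, a)
        assert rho == pytest.approx(1.0) and n == 4
        b = self._table([-0.1, -0.5, 0.3, -0.8])
        rho_neg, _, _ = dataset_concordance(a, b)
        assert rho_neg == pytest.approx(-1.0)

    def test_one_swapped_pair(self):
        a = self._table([0.1, 0.2, 0.3, 0.4])
        b = self._table([0.1, 0.3, 0.2, 0.4])
        rho, _, _ = dataset_concordance(a, b)
        assert rho == pytest.approx(0.8)

    def test_subset_restriction_and_small_overlap(self):
        a = self._table([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(Exception, match="overlapping"):
            dataset_concordance(a, a, subset=[("S", "m0"), ("S", "m1")])
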