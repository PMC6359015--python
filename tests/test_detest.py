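import math

import numpy as np
import pandas as pd
import pytest
import scipy.special
from hypothesis import given, settings
from hypothesis import strategies as st

from gxede import (
    SimulationConfig,
    ThresholdConfig,
    bh_adjust,
    call_de,
    contrast_test,
    estimate_moderation,
    fit_gene_models,
    posterior_variance,
    simulate_dataset,
    unmoderated,
)

from _oracles import bh_step_up_oracle, pooled_t_oracle
from conftest import CELLS_2x2, make_matrix


class TestFitGeneModels:
    def test_hand_least_squares_example(self, worked_example_matrix):
        fits = fit_gene_models(worked_example_matrix)
        assert fits.residual_df == 4
        np.testing.assert_allclose(
            fits.group_means.loc["g0", ["WT:ground", "WT:flight", "KO:ground", "KO:flight"]]
            .to_numpy(dtype=float),
            [3.0, 7.0, 2.0, 6.0],
        )
        assert fits.residual_var["g0"] == pytest.approx(2.0)

    def test_zero_variance_gene(self):
        fits = fit_gene_models(make_matrix(np.full((1, 8), 4.0), CELLS_2x2))
        assert fits.residual_var["g0"] == 0.0

    def test_group_shift_is_orthogonal(self, worked_example_matrix):
        base = fit_gene_models(worked_example_matrix)
        shifted = worked_example_matrix.values.copy()
        shifted.loc["g0", ["s4", "s5"]] += 10.0  # the KO ground pair
        fits = fit_gene_models(
            make_matrix(shifted.to_numpy(), CELLS_2x2)
        )
        assert fits.group_means.iloc[0]["KO:ground"] == pytest.approx(
            base.group_means.iloc[0]["KO:ground"] + 10.0
        )
        for cell in ("WT:ground", "WT:flight", "KO:flight"):
            assert fits.group_means.iloc[0][cell] == pytest.approx(
                base.group_means.iloc[0][cell]
            )

    def test_raw_scale_rejected(self):
        m = make_matrix(np.full((1, 8), 4.0), CELLS_2x2, scale="raw")
        with pytest.raises(ValueError, match="log2"):
            fit_gene_models(m)


class TestModeration:
    def test_identical_variances_give_infinite_prior_df(self):
        rng = np.random.default_rng(0)
        # different gene means but one common residual variance
        base = rng.normal(size=(50, 1))
        noise_pattern = np.array([1.0, -1.0] * 4)  # same per-cell spread everywhere
        m = make_matrix(base + 0.3 * noise_pattern, CELLS_2x2)
        fits = fit_gene_models(m)
        assert fits.residual_var.std() == pytest.approx(0.0, abs=1e-12)
        params = estimate_moderation(fits)
        assert math.isinf(params.prior_df)
        # with no dispersion every posterior variance equals s0^2; the
        # log-moment estimator corrects for the chi-square bias of s_g^2,
        # so s0^2 is the common value times exp(log(d/2) - digamma(d/2)),
        # a factor that tends to 1 as the residual df grows
        common = fits.residual_var.iloc[0]
        assert params.posterior_var.nunique() == 1
        d = fits.residual_df
        bias = math.exp(math.log(d / 2) - scipy.special.digamma(d / 2))
        assert params.prior_var == pytest.approx(common * bias, rel=1e-9)
        assert (params.posterior_var == params.prior_var).all()

    def test_parameter_recovery_from_prior(self):
        config = SimulationConfig(n_genes=10_000, seed=7, effect_size=0.0)
        config.category_counts = {}
        config.prior_df_d0, config.prior_var_s0sq = 4.0, 0.05
        matrix, _ = simulate_dataset(config)
        params = estimate_moderation(fit_gene_models(matrix))
        assert params.prior_df == pytest.approx(4.0, rel=0.20)
        assert params.prior_var == pytest.approx(0.05, rel=0.10)

    def test_no_shrinkage_limit(self, worked_example_matrix):
        fits = fit_gene_models(worked_example_matrix)
        pd.testing.assert_series_equal(
            posterior_variance(fits, 0.0, 123.0), fits.residual_var
        )

    def test_shrinkage_bound(self):
        config = SimulationConfig(n_genes=500, seed=2)
        matrix, _ = simulate_dataset(config)
        fits = fit_gene_models(matrix)
        params = estimate_moderation(fits)
        lo = np.minimum(fits.residual_var, params.prior_var)
        hi = np.maximum(fits.residual_var, params.prior_var)
        assert ((params.posterior_var >= lo - 1e-12) & (params.posterior_var <= hi + 1e-12)).all()

    def test_all_zero_variances_rejected(self):
        fits = fit_gene_models(make_matrix(np.full((3, 8), 1.0), CELLS_2x2))
        with pytest.raises(ValueError, match="positive residual variance"):
            estimate_moderation(fits)


class TestContrast:
    def test_zero_difference_gives_unit_p(self):
        vals = np.tile([1.0, -1.0], (3, 4))  # all cell means 0
        fits = fit_gene_models(make_matrix(vals, CELLS_2x2))
        res = contrast_test(fits, unmoderated(fits), "WT_flight_vs_ground")
        np.testing.assert_allclose(res["t_mod"], 0.0)
        np.testing.assert_allclose(res["p_raw"], 1.0)

    def test_unknown_comparison_rejected(self, worked_example_matrix):
        fits = fit_gene_models(worked_example_matrix)
        with pytest.raises(ValueError, match="unknown comparison"):
            contrast_test(fits, unmoderated(fits), "WT_vs_KO")

    def test_matches_pooled_t_oracle_without_moderation(self):
        config = SimulationConfig(n_genes=200, seed=5)
        matrix, _ = simulate_dataset(config)
        fits = fit_gene_models(matrix)
        res = contrast_test(fits, unmoderated(fits), "KO_vs_WT_flight")
        groups = [
            (matrix.sample_meta.loc[s, "genotype"], matrix.sample_meta.loc[s, "environment"])
            for s in matrix.sample_ids
        ]
        est, t, p = pooled_t_oracle(
            matrix.values.to_numpy(), groups, ("KO", "flight"), ("WT", "flight")
        )
        np.testing.assert_allclose(res["log2FC"], est, atol=1e-12)
        np.testing.assert_allclose(res["t_mod"], t, atol=1e-10)
        np.testing.assert_allclose(res["p_raw"], p, atol=1e-10)

    def test_knockout_sign_convention(self):
        # KO far below WT in both environments: the ground KO-vs-WT contrast
        # must report a negative log2 fold change (a deficit)
        rng = np.random.default_rng(3)
        wt = 12.0 + 0.1 * rng.normal(size=(1, 4))
        ko = 5.0 + 0.1 * rng.normal(size=(1, 4))
        vals = np.column_stack([wt[:, :2], wt[:, 2:], ko[:, :2], ko[:, 2:]])
        fits = fit_gene_models(make_matrix(vals, CELLS_2x2))
        res = contrast_test(fits, unmoderated(fits), "KO_vs_WT_ground")
        assert res["log2FC"].iloc[0] < -5

    def test_t_monotone_in_fold_change(self):
        # same variance structure, growing mean shift
        ts = []
        for shift in (0.5, 1.0, 2.0, 4.0):
            vals = np.array([[0, 1, 0 + shift, 1 + shift, 0, 1, 0, 1]], dtype=float)
            fits = fit_gene_models(make_matrix(vals, CELLS_2x2))
            res = contrast_test(fits, unmoderated(fits), "WT_flight_vs_ground")
            ts.append(abs(res["t_mod"].iloc[0]))
        assert all(b > a for a, b in zip(ts, ts[1:]))


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate_vectors(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([0.0, 0.0, 0.0]), [0.0, 0.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False), min_size=1, max_size=40
        )
    )
    def test_matches_textbook_oracle_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_step_up_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()
        # adjusted values are monotone in raw-p rank
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCallDE:
    @pytest.mark.parametrize(
        "p,lfc,expected",
        [
            (2.9e-9, -7.27, "down"),  # strongly depressed knockout target
            (0.01, -7.27, "ns"),  # p gate is strict
            (0.001, 0.9, "ns"),  # fold-change gate
            (0.001, 1.0, "ns"),  # fold-change gate is strict
            (0.0001, 3.2, "up"),
        ],
    )
    def test_threshold_gates(self, p, lfc, expected):
        result = pd.DataFrame(
            {"log2FC": [lfc], "p_raw": [p], "p_adj": [p]}, index=["g0"]
        )
        out = call_de(result, ThresholdConfig())
        assert out["status"].iloc[0] == expected

    def test_raw_versus_adjusted_switch(self):
        result = pd.DataFrame(
            {"log2FC": [3.0], "p_raw": [0.005], "p_adj": [0.02]}, index=["g0"]
        )
        assert call_de(result, ThresholdConfig())["status"].iloc[0] == "ns"
        assert (
            call_de(result, ThresholdConfig(use_adjusted_p=False))["status"].iloc[0]
            == "up"
        )

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="p_threshold"):
            ThresholdConfig(p_threshold=1.5)
        with pytest.raises(ValueError, match="lfc_threshold"):
            ThresholdConfig(lfc_threshold=-1.0)
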