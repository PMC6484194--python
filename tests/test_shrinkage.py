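"""Variance components, shrinkage weights, and the three predictors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcshrink import (
    FisherPanel,
    SyntheticConfig,
    generate_fisher_panel,
    lambda_map,
    mean_estimator,
    raw_estimator,
    shrink,
    variance_components,
)

from oracles import variance_components_loop


class TestRawEstimator:
    def test_is_identity_copy_of_session_one(self, hand_panel):
        res = raw_estimator(hand_panel)
        np.testing.assert_array_equal(res.fisher, hand_panel.session("1"))

    def test_nan_propagates(self):
        v = np.array([[[np.nan, 0.2], [0.1, 0.2]], [[0.3, 0.4], [0.3, 0.4]]])
        res = raw_estimator(FisherPanel(v))
        assert np.isnan(res.fisher[0, 0]) and res.fisher[1, 1] == 0.4

    def test_single_subject_is_valid(self):
        v = np.array([[[0.5], [0.6]]])
        res = raw_estimator(FisherPanel(v))
        np.testing.assert_array_equal(res.fisher, [[0.5]])


class TestMeanEstimator:
    def test_identical_maps_average_to_themselves(self):
        v = np.tile(np.array([0.1, 0.4]), (3, 2, 1))
        res = mean_estimator(FisherPanel(v))
        np.testing.assert_allclose(res.fisher, v[:, 0, :])

    def test_two_subject_arithmetic_mean_replicated(self):
        v = np.array([[[0.2], [0.9]], [[0.4], [0.9]]])
        res = mean_estimator(FisherPanel(v))
        np.testing.assert_allclose(res.fisher, [[0.3], [0.3]])

    def test_nan_excluded_from_average(self):
        v = np.array([[[np.nan, 0.2], [0, 0]], [[0.4, 0.4], [0, 0]]])
        res = mean_estimator(FisherPanel(v))
        np.testing.assert_allclose(res.fisher[:, 0], 0.4)
        np.testing.assert_allclose(res.fisher[:, 1], 0.3)

    def test_all_nan_voxel_stays_nan(self):
        v = np.array([[[np.nan], [0.0]], [[np.nan], [0.0]]])
        assert np.isnan(mean_estimator(FisherPanel(v)).fisher).all()

    def test_single_subject_mean_equals_raw(self):
        v = np.array([[[0.5, -0.2], [0.0, 0.0]]])
        np.testing.assert_array_equal(
            mean_estimator(FisherPanel(v)).fisher, raw_estimator(FisherPanel(v)).fisher
        )


class TestVarianceComponents:
    def test_perfect_retest_gives_zero_error_variance(self):
        v = np.random.default_rng(0).standard_normal((5, 1, 3))
        panel = FisherPanel(np.repeat(v, 2, axis=1))
        comp = variance_components(panel)
        np.testing.assert_allclose(comp.var_u, 0.0, atol=1e-15)
        lam = lambda_map(comp)
        np.testing.assert_allclose(lam.values, 0.0, atol=1e-15)

    def test_hand_computed_example(self, hand_panel):
        # D = (0.2, 0.0, 0.4), Dbar = 0.2 -> Var{U} = 0.02; session means
        # (0.1, 0.3) -> pooled Var{V} = 0.01; Var{X} clamps to 0
        comp = variance_components(hand_panel)
        np.testing.assert_allclose(comp.d_bar, [0.2])
        np.testing.assert_allclose(comp.var_u, [0.02])
        np.testing.assert_allclose(comp.var_v, [0.01])
        np.testing.assert_allclose(comp.var_x, [0.0])
        assert comp.clamped[0]

    def test_requires_two_subjects(self):
        v = np.zeros((1, 2, 3))
        with pytest.raises(ValueError, match=">=2 subjects"):
            variance_components(FisherPanel(v))

    def test_matches_loop_oracle(self, rng):
        v = rng.standard_normal((8, 2, 20))
        panel = FisherPanel(v)
        comp = variance_components(panel)
        var_u, var_v, var_x = variance_components_loop(v[:, 0, :], v[:, 1, :])
        np.testing.assert_allclose(comp.var_u, var_u, atol=1e-12)
        np.testing.assert_allclose(comp.var_v, var_v, atol=1e-12)
        np.testing.assert_allclose(comp.var_x, var_x, atol=1e-12)

    def test_nan_subjects_dropped_voxelwise(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal((6, 2, 2))
        v[0, 0, 0] = np.nan  # subject 0 incomplete at voxel 0 only
        comp = variance_components(FisherPanel(v))
        assert comp.effective_i[0] == 5 and comp.effective_i[1] == 6
        ref_u, ref_v, _ = variance_components_loop(v[1:, 0, :1], v[1:, 1, :1])
        np.testing.assert_allclose(comp.var_u[0], ref_u[0], atol=1e-12)
        np.testing.assert_allclose(comp.var_v[0], ref_v[0], atol=1e-12)

    def test_parameter_recovery_from_model_level_panel(self):
        cfg = SyntheticConfig(
            n_subjects=200, n_voxels=500, mu_x=0.3, sigma2_x=0.04, sigma2_u=0.01, rng_seed=41
        )
        panel, _ = generate_fisher_panel(cfg)
        comp = variance_components(panel)
        assert abs(comp.var_u.mean() - 0.01) < 0.002
        assert abs(comp.var_x.mean() - 0.04) < 0.008


class TestLambdaMap:
    @pytest.mark.parametrize(
        "var_x,var_u,expect", [(0.04, 0.01, 0.2), (0.05, 0.0, 0.0), (0.0, 0.01, 1.0)]
    )
    def test_arithmetic_and_limits(self, var_x, var_u, expect):
        comp = _components(var_x, var_u)
        np.testing.assert_allclose(lambda_map(comp).values, expect)

    def test_both_components_zero_gives_one(self):
        np.testing.assert_allclose(lambda_map(_components(0.0, 0.0)).values, 1.0)

    def test_fixed_lambda_constant_map(self):
        lam = lambda_map(fixed_lambda=0.1, n_voxels=7)
        assert lam.source == "fixed"
        np.testing.assert_array_equal(lam.values, 0.1)

    def test_fixed_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            lambda_map(fixed_lambda=1.5, n_voxels=3)

    def test_unestimable_voxel_uses_fallback(self):
        comp = _components(np.nan, np.nan)
        lam = lambda_map(comp, fallback=0.1)
        np.testing.assert_allclose(lam.values, 0.1)

    def test_icc_is_one_minus_lambda(self):
        lam = lambda_map(_components(0.04, 0.01))
        np.testing.assert_allclose(lam.icc, 0.8)

    def test_estimated_lambda_converges_to_truth(self):
        cfg = SyntheticConfig(
            n_subjects=200, n_voxels=500, mu_x=0.3, sigma2_x=0.04, sigma2_u=0.01, rng_seed=43
        )
        panel, truth = generate_fisher_panel(cfg)
        lam = lambda_map(variance_components(panel))
        assert abs(lam.values.mean() - truth.lambda_true.mean()) < 0.03


def _components(var_x, var_u):
    from fcshrink.shrinkage import VarianceComponents

    a = np.atleast_1d
    return VarianceComponents(
        var_u=a(np.float64(var_u)),
        var_v=a(np.float64(var_u)) + a(np.float64(var_x)),
        var_x=a(np.float64(var_x)),
        d_bar=np.zeros(1),
        clamped=np.zeros(1, dtype=bool),
        effective_i=np.full(1, 10),
    )


class TestShrink:
    def test_lambda_one_reduces_to_mean(self, model_panel):
        panel, _, _ = model_panel
        lam = lambda_map(fixed_lambda=1.0, n_voxels=panel.n_voxels)
        np.testing.assert_array_equal(
            shrink(panel, lam).fisher, mean_estimator(panel).fisher
        )

    def test_lambda_zero_reduces_to_raw(self, model_panel):
        panel, _, _ = model_panel
        lam = lambda_map(fixed_lambda=0.0, n_voxels=panel.n_voxels)
        np.testing.assert_array_equal(
            shrink(panel, lam).fisher, raw_estimator(panel).fisher
        )

    def test_midpoint_value_and_back_transform(self):
        v = np.array([[[0.2], [0.0]], [[0.6], [0.0]]])
        panel = FisherPanel(v)  # mean map = 0.4
        lam = lambda_map(fixed_lambda=0.5, n_voxels=1)
        res = shrink(panel, lam)
        np.testing.assert_allclose(res.fisher[0, 0], 0.3)
        np.testing.assert_allclose(res.correlation[0, 0], np.tanh(0.3))

    def test_voxel_set_mismatch_rejected(self, model_panel):
        panel, _, _ = model_panel
        with pytest.raises(ValueError, match="voxels"):
            shrink(panel, lambda_map(fixed_lambda=0.5, n_voxels=panel.n_voxels + 1))

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_convexity_between_raw_and_mean(self, seed):
        rng = np.random.default_rng(seed)
        panel = FisherPanel(rng.standard_normal((5, 2, 12)))
        lam = lambda_map(variance_components(panel))
        res = shrink(panel, lam)
        raw = raw_estimator(panel).fisher
        mean = mean_estimator(panel).fisher
        lo = np.minimum(raw, mean) - 1e-12
        hi = np.maximum(raw, mean) + 1e-12
        assert np.all((res.fisher >= lo) & (res.fisher <= hi))

    def test_constant_panel_is_degenerate_safe(self):
        panel = FisherPanel(np.full((4, 2, 6), 0.25))
        comp = variance_components(panel)
        lam = lambda_map(comp)
        np.testing.assert_array_equal(lam.values, 1.0)
        np.testing.assert_allclose(shrink(panel, lam).fisher, 0.25)
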