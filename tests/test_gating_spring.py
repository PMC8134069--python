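"""Gating-spring model: Boltzmann gating, stiffness/force duality, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanostat import gating_spring as gs
from mechanostat import synthetic as syn
from mechanostat.constants import K_B

T = 298.15


class TestOpenProbability:
    def test_half_open_at_setpoint(self):
        pop = gs.TransducerPopulation("sensitive", N=100, z=50e-15, X0=3e-7)
        assert gs.open_probability(3e-7, pop, T) == pytest.approx(0.5)

    def test_saturates_far_from_setpoint(self):
        pop = gs.TransducerPopulation("sensitive", N=100, z=50e-15, X0=0.0)
        far = 100 * K_B * T / pop.z
        assert gs.open_probability(far, pop, T) == pytest.approx(1.0, abs=1e-12)
        assert gs.open_probability(-far, pop, T) == pytest.approx(0.0, abs=1e-12)

    def test_one_thermal_unit_displacement(self):
        # p(X0 + kB*T/z) = 1/(1+e^-1)
        pop = gs.TransducerPopulation("sensitive", N=100, z=50e-15, X0=0.0)
        assert gs.open_probability(K_B * T / pop.z, pop, T) == pytest.approx(
            0.7310585786, abs=1e-9)

    @given(st.floats(-1e-6, 1e-6), st.floats(-1e-6, 1e-6))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing(self, x1, x2):
        if abs(x1 - x2) < 1e-9:  # below float resolution of the Boltzmann arg
            return
        pop = gs.TransducerPopulation("sensitive", N=100, z=50e-15, X0=0.0)
        p1, p2 = (gs.open_probability(x, pop, T) for x in (x1, x2))
        assert (p1 < p2) == (x1 < x2)

    def test_invalid_inputs_rejected(self):
        pop = gs.TransducerPopulation("sensitive", N=100, z=50e-15, X0=0.0)
        with pytest.raises(ValueError, match="invalid displacement"):
            gs.open_probability(np.nan, pop, T)
        with pytest.raises(ValueError, match="invalid temperature"):
            gs.open_probability(0.0, pop, -1.0)


class TestStiffnessForceDuality:
    def test_no_transducers_is_hookean(self, displacement_grid):
        params = gs.GatingSpringParams(
            populations=[gs.TransducerPopulation("sensitive", N=0.0, z=50e-15)],
            K_inf=1e-3)
        K = gs.model_stiffness(displacement_grid, params)
        np.testing.assert_allclose(K, 1e-3)
        F = gs.model_force(displacement_grid, params)
        np.testing.assert_allclose(F, 1e-3 * displacement_grid, atol=1e-30)

    def test_single_population_dip_depth(self):
        # at X = X0, p(1-p) = 1/4, so K = K_inf - N z^2 / (4 kB T)
        params = gs.GatingSpringParams(
            populations=[gs.TransducerPopulation("sensitive", N=100, z=50e-15, X0=0.0)],
            K_inf=1e-3, T=T)
        expected = 1e-3 - 100 * (50e-15) ** 2 / (4 * K_B * T)
        assert gs.model_stiffness(0.0, params) == pytest.approx(expected, rel=1e-12)

    def test_stiffness_is_force_derivative(self, two_pop_params, displacement_grid):
        # central-difference oracle pairing F and K
        h = 1e-10
        K = gs.model_stiffness(displacement_grid, two_pop_params)
        dF = (gs.model_force(displacement_grid + h, two_pop_params)
              - gs.model_force(displacement_grid - h, two_pop_params)) / (2 * h)
        np.testing.assert_allclose(dF, K, rtol=1e-6)

    def test_force_antisymmetric_for_centered_dips(self, two_pop_params):
        X = np.linspace(-1.5e-6, 1.5e-6, 31)
        F = gs.model_force(X, two_pop_params)
        np.testing.assert_allclose(F, -F[::-1], atol=1e-24)

    def test_force_zero_at_origin_and_increasing(self, two_pop_params, displacement_grid):
        F = gs.model_force(displacement_grid, two_pop_params)
        assert gs.model_force(0.0, two_pop_params) == 0.0
        assert np.all(np.diff(F) > 0)

    def test_nonphysical_parameters_rejected(self, displacement_grid):
        params = gs.GatingSpringParams(
            populations=[gs.TransducerPopulation("sensitive", N=1e6, z=100e-15, X0=0.0)],
            K_inf=1e-3, T=T)
        with pytest.raises(ValueError, match="non-physical"):
            gs.model_stiffness(displacement_grid, params)


class TestSlopeStiffnessFromForceSteps:
    def test_hookean_steps_recover_constant_stiffness(self):
        K_inf = 1e-3
        forces = np.linspace(-2e-9, 2e-9, 21)
        steps = [(f, f / K_inf) for f in forces]
        curve = gs.slope_stiffness_from_force_steps(steps)
        np.testing.assert_allclose(curve.K, K_inf, atol=1e-9)

    def test_forward_inverse_consistency(self, two_pop_params):
        forces = np.linspace(-2e-9, 2e-9, 41)
        steps = syn.gen_force_steps(two_pop_params, forces)
        curve = gs.slope_stiffness_from_force_steps(steps)
        K_true = gs.model_stiffness(curve.X, two_pop_params)
        interior = slice(3, -3)
        np.testing.assert_allclose(curve.K[interior], K_true[interior], rtol=0.02)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="insufficient force steps"):
            gs.slope_stiffness_from_force_steps([(1e-9, 1e-6)] * 3)

    def test_non_monotone_rejected(self):
        steps = [(-1e-9, -1e-6), (0.0, 0.0), (1e-9, 1e-6),
                 (2e-9, 0.5e-6), (3e-9, 2e-6)]
        with pytest.raises(ValueError, match="non-monotone"):
            gs.slope_stiffness_from_force_steps(steps)


class TestFit:
    def test_noiseless_recovery_within_1pct(self, noiseless_curve):
        params, diag = gs.fit_gating_spring(noiseless_curve, 2, T)
        flat = diag["parameters"]
        for key, truth in [("N_s", 100.0), ("z_s", 50e-15), ("N_i", 1000.0),
                           ("z_i", 10e-15), ("K_inf", 1e-3)]:
            assert flat[key] == pytest.approx(truth, rel=0.01), key

    def test_flat_curve_yields_no_nonlinearity(self, displacement_grid):
        import warnings

        curve = gs.StiffnessCurve(X=displacement_grid,
                                  K=np.full_like(displacement_grid, 1e-3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # collapse flag expected
            params, diag = gs.fit_gating_spring(curve, 2, T)
        dK_total = sum(p.N * p.z**2 / (4 * K_B * T) for p in params.populations)
        assert dK_total < 1e-3 * params.K_inf

    def test_population_order_is_stable(self, noiseless_curve):
        # label assignment by descending z must not depend on the restart draw
        for seed in (0, 1, 2):
            params, _ = gs.fit_gating_spring(
                noiseless_curve, 2, T, gs.GatingFitConfig(n_restarts=6, seed=seed))
            zs = [p.z for p in params.populations]
            assert params.populations[0].label == "sensitive"
            assert zs[0] > zs[1]

    def test_insufficient_points_rejected(self, two_pop_params):
        X = np.linspace(-1e-6, 1e-6, 10)
        curve = gs.StiffnessCurve(X=X, K=gs.model_stiffness(X, two_pop_params))
        with pytest.raises(ValueError, match="insufficient data"):
            gs.fit_gating_spring(curve, 2, T)


class TestDerivedParameters:
    def test_closed_form_stiffness_relief(self):
        # dK = N z^2 / (4 kB T) for one population
        params = gs.GatingSpringParams(
            populations=[gs.TransducerPopulation("sensitive", N=100, z=50e-15, X0=0.0)],
            K_inf=1e-3, K_steady=8e-4, T=T)
        d = gs.derived_parameters(params)
        assert d.dK_s == pytest.approx(1.518e-5, rel=1e-3)
        assert d.dK_total == d.dK_s + d.dK_i
        assert d.K_GS == pytest.approx(2e-4)

    def test_no_transducers_all_zero(self):
        params = gs.GatingSpringParams(
            populations=[gs.TransducerPopulation("sensitive", N=0.0, z=50e-15)],
            K_inf=1e-3, K_steady=8e-4, T=T)
        d = gs.derived_parameters(params)
        assert d.dK_total == 0.0 and d.NL_total == 0.0
        assert d.K_GS == pytest.approx(2e-4)

    def test_total_relief_equals_dip_depth_for_coincident_setpoints(self, two_pop_params):
        d = gs.derived_parameters(two_pop_params)
        X = np.linspace(-2e-6, 2e-6, 200001)
        dip = two_pop_params.K_inf - gs.model_stiffness(X, two_pop_params).min()
        assert dip == pytest.approx(d.dK_total, rel=1e-9)

    @pytest.mark.parametrize("N_lo,N_hi", [(50, 100), (100, 200)])
    def test_more_channels_more_relief(self, N_lo, N_hi):
        def relief(N):
            params = gs.GatingSpringParams(
                populations=[gs.TransducerPopulation("sensitive", N=N, z=50e-15)],
                K_inf=1e-3, K_steady=8e-4, T=T)
            return gs.derived_parameters(params).dK_s
        assert relief(N_hi) > relief(N_lo)

    def test_inconsistent_stiffnesses_rejected(self):
        with pytest.raises(ValueError, match="inconsistent stiffnesses"):
            gs.GatingSpringParams(
                populations=[gs.TransducerPopulation("sensitive", N=0.0, z=50e-15)],
                K_inf=1e-3, K_steady=2e-3, T=T)


class TestCompareConditions:
    def _flat(self, N_s):
        params = gs.GatingSpringParams(
            populations=[gs.TransducerPopulation("sensitive", N=N_s, z=50e-15, X0=0.0),
                         gs.TransducerPopulation("insensitive", N=1000, z=10e-15, X0=0.0)],
            K_inf=1e-3, K_steady=8e-4, T=T)
        return gs.flatten_fit(params)

    def test_identical_conditions(self):
        fits = [self._flat(100), self._flat(110)]
        table = gs.compare_conditions(fits, fits)
        defined = table["mean_a"] != 0  # X0 means are 0: ratio undefined there
        assert np.allclose(table.loc[defined, "ratio"], 1.0)
        assert np.allclose(table["p_value"], 1.0)

    def test_doubled_channel_count_gives_ratio_two(self):
        a = [self._flat(100), self._flat(100)]
        b = [self._flat(200), self._flat(200)]
        table = gs.compare_conditions(a, b)
        assert table.loc["N_s", "ratio"] == pytest.approx(2.0)

    def test_simulated_cohorts_significant(self):
        rng = np.random.default_rng(11)
        a = [self._flat(x) for x in rng.normal(100, 5, 7)]
        b = [self._flat(x) for x in rng.normal(150, 5, 7)]
        assert gs.compare_conditions(a, b).loc["N_s", "p_value"] < 0.01

    def test_mismatched_parameters_rejected(self):
        a = [self._flat(100), self._flat(100)]
        b = [dict(f, extra=1.0) for f in a]
        with pytest.raises(ValueError, match="mismatched"):
            gs.compare_conditions(a, b)
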