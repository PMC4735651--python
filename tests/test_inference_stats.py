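"""Consensus statistics, Gaussian failure expectations, van't Hoff fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nativedg.inference_stats import (
    consensus_and_cs,
    consensus_of,
    expected_cs_failures,
    precision_experiment_multiplier,
    simulate_cs_failure_rate,
    subtract_fluorophore,
    vant_hoff_fit,
)
from nativedg.thermo_core import (
    DeltaGEstimate,
    EnthalpyEntropyFit,
    ThermoCondition,
    delta_g_at_temperature,
)


def _est(value, sd, temp=25.0, buffer="PBS", label=""):
    return DeltaGEstimate(value, sd, condition=ThermoCondition(temp, buffer), label=label)


def grid_consensus(mu1, s1, mu2, s2):
    """1-D oracle: minimize the sum of squared z scores by grid refinement
    down to 1e-6 of the initial bracket."""
    lo, hi = min(mu1, mu2), max(mu1, mu2)
    span = hi - lo or 1.0
    lo, hi = lo - 0.1 * span, hi + 0.1 * span
    # two refinement stages reach ~1e-6 of the bracket; finer grids probe
    # objective differences below double precision
    for _ in range(2):
        c = np.linspace(lo, hi, 2001)
        ssz = ((c - mu1) / s1) ** 2 + ((c - mu2) / s2) ** 2
        i = int(np.argmin(ssz))
        step = (hi - lo) / 2000
        lo, hi = c[i] - step, c[i] + step
    return c[i], float(ssz[i]), step


def grid_vant_hoff(temps_k, mus, sds, dh0, ds0):
    """2-D oracle: refine a (dH, dS) grid around a seed to ~1e-4 resolution."""
    dh_lo, dh_hi = dh0 - 2.0, dh0 + 2.0
    ds_lo, ds_hi = ds0 - 5e-3, ds0 + 5e-3
    for _ in range(4):
        dh = np.linspace(dh_lo, dh_hi, 201)
        ds = np.linspace(ds_lo, ds_hi, 201)
        hh, ss = np.meshgrid(dh, ds, indexing="ij")
        ssz = np.zeros_like(hh)
        for t, mu, sd in zip(temps_k, mus, sds):
            ssz += ((hh - t * ss - mu) / sd) ** 2
        i, j = np.unravel_index(np.argmin(ssz), ssz.shape)
        dstep_h = (dh_hi - dh_lo) / 200
        dstep_s = (ds_hi - ds_lo) / 200
        dh_lo, dh_hi = dh[i] - dstep_h, dh[i] + dstep_h
        ds_lo, ds_hi = ds[j] - dstep_s, ds[j] + dstep_s
    return dh[i], ds[j], dstep_h, dstep_s


class TestSubtraction:
    def test_three_four_five(self):
        out = subtract_fluorophore(_est(-0.5, 0.04), _est(-0.3, 0.03))
        assert out.value == pytest.approx(-0.2)
        assert out.sd == pytest.approx(0.05)

    def test_identical_reactions_cancel(self):
        out = subtract_fluorophore(_est(-0.22, 0.04), _est(-0.22, 0.04))
        assert out.value == pytest.approx(0.0)

    def test_reference_numbers(self):
        out = subtract_fluorophore(_est(-0.90, 0.05), _est(-0.22, 0.038))
        assert out.value == pytest.approx(-0.68)
        assert out.sd == pytest.approx(math.hypot(0.05, 0.038), rel=1e-12)
        assert out.sd == pytest.approx(0.0628, abs=2e-4)

    def test_condition_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            subtract_fluorophore(_est(0.0, 0.1, temp=25.0), _est(0.0, 0.1, temp=37.0))


class TestConsensus:
    def test_identical_estimates_score_ten(self):
        res = consensus_and_cs(_est(-0.4, 0.05), _est(-0.4, 0.05))
        assert res.cs == pytest.approx(10.0)
        assert res.consensus.value == pytest.approx(-0.4)

    def test_one_sd_each_scores_eight(self):
        res = consensus_and_cs(_est(-0.25, 0.05), _est(-0.15, 0.05))
        assert res.cs == pytest.approx(8.0)
        assert abs(res.z_rox) == pytest.approx(1.0)
        assert abs(res.z_alexa) == pytest.approx(1.0)

    def test_two_point_two_four_sd_scores_zero(self):
        # each measurement sqrt(5) ~ 2.236 s.d. from the consensus
        sd = 0.05
        half_gap = math.sqrt(5.0) * sd
        res = consensus_and_cs(_est(-half_gap, sd), _est(half_gap, sd))
        assert res.cs == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_equals_sum_sq_z(self):
        e1, e2 = _est(-0.31, 0.04), _est(-0.18, 0.07)
        res = consensus_and_cs(e1, e2)
        closed = 10.0 - (e1.value - e2.value) ** 2 / (e1.sd**2 + e2.sd**2)
        assert res.cs == pytest.approx(closed, rel=1e-12)

    @given(
        mu1=st.floats(-1.0, 1.0),
        mu2=st.floats(-1.0, 1.0),
        s1=st.floats(0.01, 0.2),
        s2=st.floats(0.01, 0.2),
    )
    def test_symmetry_and_betweenness(self, mu1, mu2, s1, s2):
        res_a = consensus_and_cs(_est(mu1, s1), _est(mu2, s2))
        res_b = consensus_and_cs(_est(mu2, s2), _est(mu1, s1))
        assert res_a.consensus.value == pytest.approx(res_b.consensus.value, abs=1e-12)
        assert res_a.cs == pytest.approx(res_b.cs, abs=1e-9)
        assert min(mu1, mu2) - 1e-12 <= res_a.consensus.value <= max(mu1, mu2) + 1e-12

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(5):
            mu1, mu2 = rng.uniform(-1, 1, 2)
            s1, s2 = rng.uniform(0.02, 0.2, 2)
            res = consensus_and_cs(_est(float(mu1), float(s1)), _est(float(mu2), float(s2)))
            c_star, ssz_star, step = grid_consensus(mu1, s1, mu2, s2)
            assert res.consensus.value == pytest.approx(c_star, abs=2 * step)
            assert 10.0 - res.cs == pytest.approx(ssz_star, abs=1e-6)

    def test_generalizes_beyond_two(self):
        consensus, ssz = consensus_of([_est(0.0, 0.1), _est(0.1, 0.1), _est(0.2, 0.1)])
        assert consensus.value == pytest.approx(0.1)
        assert ssz == pytest.approx(2.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            consensus_and_cs(_est(0.0, 0.0), _est(0.1, 0.1))


class TestGaussianExpectation:
    def test_reference_panel_expectation(self):
        expected = expected_cs_failures(160, 0.0)
        assert expected == pytest.approx(160 * 2 * (1 - 0.9873263406612659), abs=0.01)
        assert expected == pytest.approx(4.06, abs=0.01)
        assert expected / 160 == pytest.approx(0.0253, abs=5e-4)

    def test_boundary_threshold(self):
        assert expected_cs_failures(123, 10.0) == pytest.approx(123.0)

    def test_one_sd_threshold(self):
        assert expected_cs_failures(160, 8.0) == pytest.approx(50.7, abs=0.1)

    def test_threshold_above_ten_rejected(self):
        with pytest.raises(ValueError):
            expected_cs_failures(160, 10.5)

    def test_simulation_reproduces_expectation(self):
        rate = simulate_cs_failure_rate(10_000, seed=2024)
        assert rate == pytest.approx(0.025, abs=0.005)

    def test_independent_errors_fail_far_less_often(self):
        rate = simulate_cs_failure_rate(10_000, seed=2024, independent_errors=True)
        assert rate < 0.005


class TestPrecisionComparison:
    def test_melt_vs_catalysis_reference_ratio(self):
        ratio, multiplier = precision_experiment_multiplier(0.54, 0.038)
        assert round(ratio) == 14
        assert round(ratio) ** 2 == 196
        assert multiplier == pytest.approx(ratio**2)


class TestVantHoff:
    def test_two_points_interpolate(self):
        ests = [_est(-0.30, 0.05, temp=10.0), _est(-0.20, 0.05, temp=45.0)]
        fit = vant_hoff_fit(ests)
        assert fit.sum_sq_z == pytest.approx(0.0, abs=1e-18)
        for e in ests:
            assert delta_g_at_temperature(fit, e.condition) == pytest.approx(e.value)

    def test_noiseless_recovery_of_reference_fit(self):
        truth = EnthalpyEntropyFit(-0.81, -1.89e-3)
        ests = [
            _est(delta_g_at_temperature(truth, ThermoCondition(t, "PBS")), 1e-9, temp=t)
            for t in (10.0, 25.0, 37.0, 45.0)
        ]
        fit = vant_hoff_fit(ests)
        assert fit.dh == pytest.approx(-0.81, rel=1e-6)
        assert fit.ds == pytest.approx(-1.89e-3, rel=1e-6)

    def test_matches_grid_oracle_on_weighted_instance(self, rng):
        temps = [10.0, 25.0, 37.0, 45.0]
        ests = [
            _est(float(rng.uniform(-0.4, -0.1)), float(rng.uniform(0.02, 0.1)), temp=t)
            for t in temps
        ]
        fit = vant_hoff_fit(ests)
        dh_star, ds_star, step_h, step_s = grid_vant_hoff(
            [e.condition.kelvin for e in ests],
            [e.value for e in ests],
            [e.sd for e in ests],
            fit.dh,
            fit.ds,
        )
        assert fit.dh == pytest.approx(dh_star, abs=2 * step_h)
        assert fit.ds == pytest.approx(ds_star, abs=2 * step_s)

    def test_equal_weights_reduce_to_ols(self, rng):
        temps = np.array([10.0, 25.0, 37.0, 45.0])
        values = rng.uniform(-0.5, 0.0, len(temps))
        ests = [_est(float(v), 0.05, temp=float(t)) for t, v in zip(temps, values)]
        fit = vant_hoff_fit(ests)
        slope, intercept = np.polyfit(temps + 273.15, values, 1)
        assert fit.ds == pytest.approx(-slope, rel=1e-9)
        assert fit.dh == pytest.approx(intercept, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct temperatures"):
            vant_hoff_fit([_est(-0.3, 0.1, temp=25.0), _est(-0.2, 0.1, temp=25.0)])
        with pytest.raises(ValueError, match="sd > 0"):
            vant_hoff_fit([_est(-0.3, 0.0, temp=25.0), _est(-0.2, 0.1, temp=37.0)])
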