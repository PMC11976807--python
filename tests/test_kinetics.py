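import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import hipecpk as hp
from hipecpk.kinetics import map_central_parameterization

from conftest import random_pk_params


def ode_concentration(p: hp.PKParams, t_eval):
    """Independent oracle: numerically integrate the stated ODE system."""

    def rhs(t, y):
        return [p.k_in * (t <= p.t_in) - p.k_e * y[0]]

    sol = solve_ivp(
        rhs,
        [0.0, float(np.max(t_eval))],
        [0.0],
        t_eval=np.atleast_1d(t_eval),
        rtol=1e-10,
        atol=1e-13,
        max_step=5.0,
    )
    return sol.y[0]


class TestConcentration:
    def test_starts_at_zero(self):
        p = hp.PKParams(0.1, 100.0, 0.02)
        assert hp.concentration_at(p, 0.0) == 0.0

    def test_plateau_is_kin_over_ke(self):
        p = hp.PKParams(0.1, 1e7, 0.02)
        assert hp.concentration_at(p, 1e6) == pytest.approx(5.0, rel=1e-9)

    def test_matches_ode_oracle(self):
        p = hp.PKParams(0.03, 110.0, math.log(2) / 30.0)
        t = np.array([15.0, 60.0, 109.0, 111.0, 240.0, 480.0])
        np.testing.assert_allclose(hp.concentration_at(p, t), ode_concentration(p, t), rtol=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            hp.concentration_at(hp.PKParams(0.1, 100.0, 0.02), -1.0)

    def test_continuous_and_unimodal(self):
        p = hp.PKParams(0.05, 120.0, 0.03)
        t = np.linspace(0.0, 480.0, 4801)
        c = hp.concentration_at(p, t)
        i_peak = int(np.argmax(c))
        assert t[i_peak] == pytest.approx(p.t_in, abs=0.2)
        assert np.all(np.diff(c[: i_peak + 1]) > 0)
        assert np.all(np.diff(c[i_peak + 1 :]) < 0)
        # no jump at the input cutoff
        eps = 1e-9
        assert hp.concentration_at(p, p.t_in + eps) == pytest.approx(hp.concentration_at(p, p.t_in), rel=1e-6)


class TestIntervalAverage:
    def test_plateau_average(self):
        p = hp.PKParams(0.1, 1e8, 0.05)
        assert hp.interval_average(p, 1e6, 2e6) == pytest.approx(2.0, rel=1e-9)

    def test_vanishing_interval_at_origin(self):
        p = hp.PKParams(0.05, 100.0, 0.03)
        assert hp.interval_average(p, 0.0, 1e-6) == pytest.approx(0.0, abs=1e-6)

    def test_straddles_input_cutoff(self):
        p = hp.PKParams(0.05, 100.0, 0.03)
        num, _ = quad(lambda t: hp.concentration_at(p, t), 90.0, 120.0, points=[100.0], epsabs=1e-12)
        assert hp.interval_average(p, 90.0, 120.0) == pytest.approx(num / 30.0, rel=1e-9)

    def test_bad_interval_rejected(self):
        p = hp.PKParams(0.05, 100.0, 0.03)
        with pytest.raises(ValueError):
            hp.interval_average(p, 60.0, 60.0)


class TestDerivedParameters:
    def test_half_life_definition(self):
        p = hp.PKParams(0.05, 100.0, math.log(2) / 30.0)
        assert hp.derived_parameters(p, 480.0).t_half == pytest.approx(30.0)

    def test_zero_input_rate(self):
        d = hp.derived_parameters(hp.PKParams(0.0, 100.0, 0.02), 480.0)
        assert d.c_max == 0.0 and d.auc_0_last == 0.0

    def test_auc_matches_dense_trapezoid(self):
        p = hp.PKParams(0.05, 110.0, 0.03)
        t = np.arange(0.0, 480.0 + 0.01, 0.01)
        expected = np.trapezoid(hp.concentration_at(p, t), t)
        assert hp.derived_parameters(p, 480.0).auc_0_last == pytest.approx(expected, rel=1e-6)

    def test_peak_at_input_end(self):
        p = hp.PKParams(0.05, 110.0, 0.03)
        d = hp.derived_parameters(p, 480.0)
        assert d.t_max == p.t_in
        assert d.c_max == pytest.approx(hp.concentration_at(p, p.t_in))

    def test_unreached_peak_clamped_with_warning(self):
        p = hp.PKParams(0.05, 110.0, 0.03)
        with pytest.warns(UserWarning):
            d = hp.derived_parameters(p, 60.0)
        assert d.t_max == 60.0


class TestOracleEquivalenceRandomDraws:
    def test_closed_form_vs_ode_100_draws(self):
        rng = np.random.default_rng(42)
        t = np.array([10.0, 50.0, 105.0, 200.0, 480.0])
        for _ in range(100):
            p = random_pk_params(rng)
            ode = ode_concentration(p, t)
            closed = hp.concentration_at(p, t)
            np.testing.assert_allclose(closed, ode, rtol=1e-6, atol=1e-12)

    def test_auc_vs_quadrature_100_draws(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            p = random_pk_params(rng)
            num, _ = quad(lambda s: hp.concentration_at(p, s), 0.0, 480.0, points=[p.t_in], limit=200)
            assert hp.cumulative_auc(p, 480.0) == pytest.approx(num, rel=1e-9)


class TestScaleEquivariance:
    def test_kin_scaling(self):
        rng = np.random.default_rng(5)
        p = random_pk_params(rng)
        p2 = hp.PKParams(3.0 * p.k_in, p.t_in, p.k_e)
        t = np.linspace(1.0, 480.0, 50)
        np.testing.assert_allclose(hp.concentration_at(p2, t), 3.0 * hp.concentration_at(p, t), rtol=1e-12)
        d1, d2 = hp.derived_parameters(p, 480.0), hp.derived_parameters(p2, 480.0)
        assert d2.c_max == pytest.approx(3.0 * d1.c_max)
        assert d2.auc_0_last == pytest.approx(3.0 * d1.auc_0_last)
        assert d2.t_max == d1.t_max and d2.t_half == d1.t_half


def simulate_reservoir(c0, rate, doses, volume_scale, dt=0.001, t_end=400.0):
    """Discrete-event oracle for the central-compartment depletion walk."""
    content = c0
    dose_map = {}
    for t, a in doses:
        dose_map.setdefault(round(t / dt), 0.0)
        dose_map[round(t / dt)] += a * volume_scale
    active = []
    on = False
    start = None
    n = int(t_end / dt)
    for i in range(n):
        content += dose_map.get(i, 0.0)
        if content > 0 and not on:
            on, start = True, i * dt
        if content > 0:
            content = max(content - rate * dt, 0.0)
            if content == 0.0:
                active.append((start, (i + 1) * dt))
                on = False
    if on:
        active.append((start, n * dt))
    return active


class TestCentralMapping:
    def test_contiguous_depletion_time(self):
        # content/rate = 110 min with boluses inside the window
        m = map_central_parameterization(1.0, 0.05, [(0.0, 2.25), (30.0, 1.125), (60.0, 1.125)])
        assert m.contiguous
        assert m.params.t_in == pytest.approx((1.0 + 4.5) / 0.05)

    def test_empty_system(self):
        m = map_central_parameterization(0.0, 0.05, [])
        assert m.params.k_in == 0.0 and m.windows == ()

    def test_zero_rate_with_content_rejected(self):
        with pytest.raises(ValueError):
            map_central_parameterization(1.0, 0.0, [(0.0, 1.0)])

    def test_depletion_gap_matches_event_simulation(self):
        # first bolus runs out before the second arrives -> two input windows
        doses = [(0.0, 1.0), (60.0, 1.0)]
        m = map_central_parameterization(0.0, 0.05, doses)
        oracle = simulate_reservoir(0.0, 0.05, doses, 1.0)
        assert not m.contiguous
        assert len(m.windows) == len(oracle) == 2
        for (a, b), (oa, ob) in zip(m.windows, oracle):
            assert a == pytest.approx(oa, abs=0.01)
            assert b == pytest.approx(ob, abs=0.01)
        assert m.params.t_in == pytest.approx(sum(b - a for a, b in oracle), abs=0.02)
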