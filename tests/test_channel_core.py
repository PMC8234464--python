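"""Gating equations, transforms, conservation and stationary behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from navpop.channel_core import (
    BathConditions,
    ChannelState,
    FactorVector,
    current,
    gate_rates,
    hss,
    inverse_transform,
    jss,
    mss,
    nernst,
    ode_rhs,
    open_probability,
    stationary_state,
    tau_hf,
    tau_hs,
    tau_j,
    tau_m,
    transform_factors,
)

finite_factors = st.lists(
    st.floats(min_value=-3, max_value=3, allow_nan=False), min_size=25, max_size=25
)


class TestTransforms:
    def test_reference_values(self):
        p = transform_factors(FactorVector.default())
        assert p.GNa == pytest.approx(1.0)  # GNaFactor = 0
        assert transform_factors(
            FactorVector.default().replace(GNaFactor=math.log(2))).GNa == pytest.approx(2.0)
        p0 = transform_factors(FactorVector.default().replace(AhfFactor=0.0))
        assert p0.Ahf == pytest.approx(0.5)

    def test_positivity_and_fraction(self):
        fv = FactorVector(np.linspace(-2, 2, 25))
        p = transform_factors(fv)
        for name in ("GNa", "mss_slope", "tau_m_max", "baseline", "tau_j_slope2"):
            assert getattr(p, name) > 0
        assert 0 < p.Ahf < 1

    @given(vals=finite_factors)
    @settings(max_examples=30, deadline=None)
    def test_round_trip(self, vals):
        fv = FactorVector(np.array(vals))
        back = inverse_transform(transform_factors(fv))
        assert np.allclose(back.values, fv.values, atol=1e-12)

    def test_rejects_non_finite_and_wrong_length(self):
        with pytest.raises(ValueError):
            FactorVector(np.full(25, np.nan))
        with pytest.raises(ValueError):
            FactorVector(np.zeros(24))

    def test_json_round_trip(self):
        fv = FactorVector.default()
        assert FactorVector.from_json(fv.to_json()).to_dict() == fv.to_dict()


class TestSteadyStateCurves:
    def test_mss_midpoint_and_shape(self, default_params):
        p = default_params
        assert mss(-p.mss_shift, p) == pytest.approx(0.5)
        assert mss(-p.mss_shift + p.mss_slope, p) == pytest.approx(
            1 / (1 + math.e**-1), abs=1e-4)
        v = np.linspace(-120, 60, 50)
        assert np.all(np.diff(mss(v, p)) > 0)
        assert mss(500.0, p) == pytest.approx(1.0, abs=1e-6)

    def test_hss_jss_midpoint_and_shape(self, default_params):
        p = default_params
        assert hss(p.hss_shift, p) == pytest.approx(0.5)
        assert hss(p.hss_shift + p.hss_slope, p) == pytest.approx(
            1 / (1 + math.e), abs=1e-4)
        assert jss(p.jss_shift, p) == pytest.approx(0.5)
        v = np.linspace(-160, 20, 50)
        assert np.all(np.diff(hss(v, p)) < 0)
        assert np.all(np.diff(jss(v, p)) < 0)
        assert hss(-500.0, p) == pytest.approx(1.0, abs=1e-6)


class TestTimeConstants:
    @pytest.mark.parametrize(
        "fn,shift_attr,max_attr,base_scale",
        [
            (tau_m, "tau_m_shift", "tau_m_max", 1 / 15),
            (tau_hf, "tau_hf_shift", "tau_hf_max", 1 / 10),
            (tau_hs, "tau_hs_shift", "tau_hs_max", 1.0),
            (tau_j, "tau_j_shift", "tau_j_max", 1.0),
        ],
    )
    def test_value_at_shift_and_asymptotes(self, default_params, fn, shift_attr,
                                           max_attr, base_scale):
        p = default_params
        shift = getattr(p, shift_attr)
        expected = p.baseline * base_scale + getattr(p, max_attr) / 2
        assert fn(shift, p) == pytest.approx(expected, rel=1e-12)
        for v in (-500.0, 500.0):
            assert fn(v, p) == pytest.approx(p.baseline * base_scale, rel=1e-6)
        assert np.all(fn(np.linspace(-150, 80, 40), p) > 0)

    def test_slow_baseline_is_tenfold_fast(self, default_params):
        # shared baseline parameter, scaled 1/10 for hf and 1 for hs
        p = default_params
        assert tau_hs(500.0, p) == pytest.approx(10 * tau_hf(500.0, p), rel=1e-6)


class TestRatesAndOde:
    @pytest.mark.parametrize("ss,tau,expected", [
        (0.5, 2.0, (0.25, 0.25)),
        (0.9, 1.0, (0.9, 0.1)),
    ])
    def test_gate_rates_examples(self, ss, tau, expected):
        alpha, beta = gate_rates(ss, tau)
        assert (alpha, beta) == pytest.approx(expected)

    @given(ss=st.floats(0.01, 0.99), tau=st.floats(0.05, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_gate_rates_recover_ss_and_tau(self, ss, tau):
        alpha, beta = gate_rates(ss, tau)
        assert alpha / (alpha + beta) == pytest.approx(ss, rel=1e-12)
        assert 1.0 / (alpha + beta) == pytest.approx(tau, rel=1e-12)

    def test_gate_rates_invalid(self):
        with pytest.raises(ValueError):
            gate_rates(1.0, 1.0)
        with pytest.raises(ValueError):
            gate_rates(0.5, -1.0)

    def test_conservation_any_state(self, default_params, rng):
        # derivative sums vanish exactly module by module
        for _ in range(5):
            raw = rng.random(8)
            d = ode_rhs(raw, float(rng.uniform(-100, 40)), default_params)
            assert d[0] + d[1] == pytest.approx(0.0, abs=1e-15)
            assert d[2] + d[3] + d[4] == pytest.approx(0.0, abs=1e-15)
            assert d[5] + d[6] + d[7] == pytest.approx(0.0, abs=1e-15)

    def test_stationary_state_is_fixed_point(self, default_params):
        for v in (-120.0, -80.0, -20.0):
            s = stationary_state(v, default_params)
            s.validate()
            assert np.abs(ode_rhs(s, v, default_params)).max() < 1e-12

    def test_stationary_limits(self, default_params):
        neg = stationary_state(-200.0, default_params)
        assert neg.Om < 1e-6 and neg.Af > 0.999 and neg.As > 0.999
        pos = stationary_state(60.0, default_params)
        assert pos.Om > 0.999 and pos.Af < 0.01

    def test_stationary_matches_long_integration(self, default_params):
        v = -35.0
        s0 = stationary_state(-120.0, default_params).as_array()
        res = solve_ivp(lambda t, y: ode_rhs(y, v, default_params),
                        (0, 20000.0), s0, method="BDF", rtol=1e-10, atol=1e-12)
        target = stationary_state(v, default_params).as_array()
        assert np.allclose(res.y[:, -1], target, atol=1e-6)

    def test_activation_matches_two_state_closed_form(self, default_params):
        # after a step, Om follows m_inf + (m0 - m_inf) exp(-t/tau) to 1e-6
        p = default_params
        v = -30.0
        s0 = stationary_state(-120.0, p).as_array()
        res = solve_ivp(lambda t, y: ode_rhs(y, v, p), (0, 10.0), s0,
                        method="BDF", rtol=1e-10, atol=1e-12, dense_output=True)
        m_inf = float(mss(v, p))
        tau = float(tau_m(v, p))
        for t in (0.1, 0.5, 1.0, 3.0, 8.0):
            analytic = m_inf + (s0[0] - m_inf) * math.exp(-t / tau)
            assert res.sol(t)[0] == pytest.approx(analytic, abs=1e-6)


class TestOpenProbabilityAndCurrent:
    def test_examples(self):
        s = ChannelState(Om=0.5, Cm=0.5, Af=0.8, Cf=0.1, If=0.1,
                         As=0.4, Cs=0.3, Is=0.3)
        assert open_probability(s, 0.6) == pytest.approx(0.125 * (0.48 + 0.16))
        full = ChannelState(1, 0, 1, 0, 0, 1, 0, 0)
        assert open_probability(full, 0.5) == pytest.approx(1.0)
        closed = ChannelState(0, 1, 1, 0, 0, 1, 0, 0)
        assert open_probability(closed, 0.5) == 0.0

    def test_current_examples(self, default_params):
        s = stationary_state(-120.0, default_params)
        assert current(73.0, s, default_params, 73.0) == 0.0
        from dataclasses import replace
        p = replace(default_params, GNa=1.0, Ahf=0.5)
        s = ChannelState(Om=0.1 ** (1 / 3), Cm=1 - 0.1 ** (1 / 3),
                         Af=1.0, Cf=0, If=0, As=1.0, Cs=0, Is=0)
        assert current(-27.0, s, p, 73.0) == pytest.approx(-10.0, rel=1e-9)

    def test_ahf_one_masks_slow_pathway(self, default_params):
        from dataclasses import replace
        p1 = replace(default_params, Ahf=1.0 - 1e-12,
                     tau_hs_max=1e6, tau_hs_shift=0.0)
        p2 = replace(default_params, Ahf=1.0 - 1e-12)
        s = stationary_state(-120.0, p1).as_array()
        # with Ahf ~ 1 the current is insensitive to slow-inactivation params
        i1 = current(-20.0, s, p1, 70.0)
        i2 = current(-20.0, s, p2, 70.0)
        assert i1 == pytest.approx(i2, rel=1e-9)


class TestNernst:
    def test_reference_value(self):
        e = nernst(BathConditions(temperature=37.0, Na_out=140.0, Na_in=9.1))
        assert e == pytest.approx(73.0, abs=0.2)

    def test_invariances(self):
        assert nernst(BathConditions(22.0, 10.0, 10.0)) == 0.0
        a = nernst(BathConditions(22.0, 140.0, 9.1))
        b = nernst(BathConditions(22.0, 280.0, 18.2))
        assert a == pytest.approx(b, rel=1e-12)

    def test_invalid_concentration(self):
        with pytest.raises(ValueError):
            BathConditions(22.0, -1.0, 9.1)
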