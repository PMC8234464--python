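"""Protocol simulation, normalisation, and reversal-potential QC."""

import math
from dataclasses import replace

import numpy as np
import pytest

from navpop.channel_core import BathConditions, mss, nernst, transform_factors
from navpop.clamp_protocols import (
    CurveData,
    ProtocolSpec,
    QCUndetermined,
    default_protocol,
    empirical_reversal,
    normalize_iv,
    qc_reversal,
    run_iv,
    run_protocol,
    run_recovery,
    run_ssa,
    run_ssi,
    run_trace,
)

BATH_LOW_NA = BathConditions(temperature=22.0, Na_out=50.0, Na_in=9.1)


class TestIV:
    def test_signs_and_zero_at_reversal(self, default_params):
        e_na = nernst(BATH_LOW_NA)
        vs = [-60.0, -30.0, 0.0, e_na, e_na + 15.0]
        spec = ProtocolSpec(kind="IV", test_potentials=vs, bath=BATH_LOW_NA)
        curve = run_iv(default_params, spec)
        assert curve.y[3] == pytest.approx(0.0, abs=1e-12)
        assert np.all(curve.y[:3] <= 0)  # below E_Na: inward (negative)
        assert curve.y[4] > 0

    def test_analytic_matches_bdf(self, default_params):
        spec = ProtocolSpec(kind="IV", test_potentials=(-50., -30., -10., 10.),
                            bath=BATH_LOW_NA)
        a = run_iv(default_params, spec, method="analytic")
        b = run_iv(default_params, spec, method="bdf")
        scale = np.abs(b.y).max()
        assert np.all(np.abs(a.y - b.y) / scale < 0.01)

    def test_bdf_tolerance_convergence(self, default_params):
        # tightening rtol/atol tenfold moves peaks by well under 0.5%
        spec = ProtocolSpec(kind="IV", test_potentials=(-40., -20., 0.),
                            bath=BATH_LOW_NA)
        coarse = run_iv(default_params, spec, method="bdf", rtol=1e-3, atol=1e-6)
        fine = run_iv(default_params, spec, method="bdf", rtol=1e-4, atol=1e-7)
        assert np.all(np.abs(coarse.y - fine.y) / np.abs(fine.y).max() < 0.005)

    def test_deterministic(self, default_params):
        spec = default_protocol("IV")
        a = run_iv(default_params, spec)
        b = run_iv(default_params, spec)
        assert np.array_equal(a.y, b.y)


class TestSSA:
    def test_normalisation_contract_and_monotone(self, default_params):
        curve = run_ssa(default_params, default_protocol("SSA"))
        assert curve.y.min() == 0.0
        assert curve.y.max() == 1.0
        assert np.all(np.diff(curve.y) >= -1e-9)

    def test_frozen_inactivation_reduces_to_mss_cubed(self, default_factors):
        # inactivation pushed to absurdly slow time scales: the normalised
        # conductance curve collapses onto min-max normalised mss^3
        slow = default_factors.replace(
            tau_hf_max_factor=math.log(1e7), tau_hs_max_factor=math.log(1e7),
            tau_j_max_factor=math.log(1e7),
            tau_hf_slope1_factor=math.log(1e3), tau_hf_slope2_factor=math.log(1e3),
            tau_hs_slope1_factor=math.log(1e3), tau_hs_slope2_factor=math.log(1e3),
            tau_j_slope1_factor=math.log(1e3), tau_j_slope2_factor=math.log(1e3))
        p = transform_factors(slow)
        curve = run_ssa(p, default_protocol("SSA"))
        ref = mss(curve.x, p) ** 3
        ref = (ref - ref.min()) / (ref.max() - ref.min())
        assert np.allclose(curve.y, ref, atol=0.02)


class TestSSI:
    def test_self_normalisation_and_shape(self, default_params):
        curve = run_ssi(default_params, default_protocol("SSI"))
        assert curve.y[0] == 1.0
        assert np.all(np.diff(curve.y) <= 1e-9)

    def test_conditioning_duration_matters_when_slow(self, default_factors):
        p = transform_factors(default_factors.replace(
            tau_hs_max_factor=math.log(3000.0)))
        base = default_protocol("SSI")
        long = run_ssi(p, replace(base, conditioning_duration=512.0))
        short = run_ssi(p, replace(base, conditioning_duration=256.0))
        assert np.abs(long.y - short.y).max() > 0.01


class TestRecovery:
    def test_asymptote_and_monotonicity(self, default_params):
        curve = run_recovery(default_params, default_protocol("REC"))
        assert np.all(np.diff(curve.y) >= -1e-9)
        assert curve.y[-1] == pytest.approx(1.0, abs=0.02)

    def test_more_negative_recovery_is_faster(self, default_params):
        base = default_protocol("REC")
        shallow = run_recovery(default_params, replace(base, recovery_potential=-100.0))
        deep = run_recovery(default_params, replace(base, recovery_potential=-140.0))
        mid = slice(1, 6)  # compare on the rising phase
        assert np.all(deep.y[mid] >= shallow.y[mid])
        assert deep.y[mid].mean() > shallow.y[mid].mean() + 0.01


class TestTrace:
    def test_decay_and_peak_consistency(self, default_params):
        spec = ProtocolSpec(kind="TRACE", pulse_potential=-20.0,
                            test_duration=50.0, sample_dt=0.02, bath=BATH_LOW_NA)
        trace = run_trace(default_params, spec)
        assert abs(trace.y[-1]) < 0.02 * np.abs(trace.y).max()
        iv = run_iv(default_params, ProtocolSpec(
            kind="IV", test_potentials=(-20.0,), bath=BATH_LOW_NA,
            test_duration=50.0))
        assert np.abs(trace.y).max() == pytest.approx(abs(iv.y[0]), rel=2e-3)

    def test_late_fraction_falls_with_fast_dominance(self, default_factors):
        spec = ProtocolSpec(kind="TRACE", pulse_potential=-20.0,
                            test_duration=40.0, sample_dt=0.05, bath=BATH_LOW_NA)
        ratios = []
        for ahf_factor in (-2.0, 3.0):  # Ahf 0.12 -> 0.95
            p = transform_factors(default_factors.replace(AhfFactor=ahf_factor))
            trace = run_trace(p, spec)
            k_late = int(20.0 / spec.sample_dt)
            ratios.append(abs(trace.y[k_late]) / np.abs(trace.y).max())
        assert ratios[1] < ratios[0]


class TestNormalizeIV:
    def test_two_step_rule(self):
        c = CurveData([-60., -30., 0.], [-200., -850., -400.],
                      capacitance_normalized=False, units="pA")
        out = normalize_iv(c)
        assert np.allclose(out.y, [-0.485, -1.0, -0.686], atol=1e-3)
        assert out.y.min() == -1.0

    def test_capacitance_normalised_only_sqrt(self):
        c = CurveData([0., 1., 2.], [-4., -1., 0.],
                      capacitance_normalized=True, units="pA/pF")
        out = normalize_iv(c)
        assert np.allclose(out.y, [-2., -1., 0.])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_iv(CurveData([0., 1.], [0., 0.]))


class TestReversalQC:
    def test_interpolated_crossing(self):
        c = CurveData([40., 60., 80.], [-20., -5., 5.])
        assert empirical_reversal(c) == pytest.approx(70.0)

    def test_exact_zero_sample(self):
        c = CurveData([40., 60., 80.], [-20., 0., 5.])
        assert empirical_reversal(c) == 60.0

    def test_model_curve_recovers_nernst(self, default_params):
        spec = default_protocol("IV", bath=BATH_LOW_NA)
        curve = run_iv(default_params, spec)
        e = empirical_reversal(curve)
        assert abs(e - nernst(BATH_LOW_NA)) <= 10.0  # one grid step

    def test_threshold_rule(self):
        bath = BathConditions(22.0, 50.0, 9.1)
        e_na = nernst(bath)
        for dev, verdict in ((12.0, "exclude"), (6.0, "keep_shifted"),
                             (0.0, "keep_shifted")):
            x = np.array([e_na + dev - 40.0, e_na + dev - 20.0, e_na + dev + 20.0])
            c = CurveData(x, np.array([-30.0, -20.0, 20.0]))
            got, shifted, measured = qc_reversal(c, bath)
            assert got == verdict
            if verdict == "keep_shifted":
                assert measured == pytest.approx(dev, abs=1e-9)
                # shifted so the empirical reversal lands on the Nernst value
                assert empirical_reversal(shifted) == pytest.approx(e_na, abs=1e-9)

    def test_no_crossing_excludes(self):
        c = CurveData([0., 20., 40.], [-5., -3., -1.])
        with pytest.raises(QCUndetermined):
            empirical_reversal(c)
        verdict, _, _ = qc_reversal(c, BathConditions(22.0, 50.0, 9.1))
        assert verdict == "exclude"


class TestProtocolSpec:
    def test_kind_specific_requirements(self):
        with pytest.raises(ValueError):
            ProtocolSpec(kind="IV")
        with pytest.raises(ValueError):
            ProtocolSpec(kind="REC")
        with pytest.raises(ValueError):
            ProtocolSpec(kind="IV", test_potentials=(0.,), test_duration=-1.0)

    def test_json_round_trip_and_dispatch(self, default_params):
        spec = default_protocol("REC")
        again = ProtocolSpec.from_dict(spec.to_dict())
        a = run_protocol(default_params, spec)
        b = run_protocol(default_params, again)
        assert np.array_equal(a.y, b.y)
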