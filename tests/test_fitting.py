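"""Curve fitting and the measurement pipeline: perfect-data oracles,
round-trip identifiability, and the persistent-current rules."""

import numpy as np
import pytest

from navclamp.calibrate import calibrated_setup, characterize_variant
from navclamp.clamp import run_voltage_clamp
from navclamp.fitting import (
    FitError,
    activation_analysis,
    default_recovery_mode,
    fit_boltzmann,
    fit_exponential,
    inactivation_analysis,
    measure_persistent,
    recovery_analysis,
)
from navclamp.gating import boltzmann_fraction
from navclamp.protocols import RecordingConditions, standard_protocols


def _run(params, cond, name, dt=0.02):
    return run_voltage_clamp(params, standard_protocols()[name], cond, dt)


class TestFitBoltzmann:
    def test_perfect_data_recovery(self):
        V = np.arange(-60, 10, 5.0)
        y = boltzmann_fraction(V, -30.0, 6.0, "rising")
        fit = fit_boltzmann(np.column_stack([V, y]), "rising")
        assert fit.v_half == pytest.approx(-30.0, abs=1e-4)
        assert fit.k == pytest.approx(6.0, abs=1e-4)

    def test_perfect_falling_recovery(self):
        V = np.arange(-80, 0, 5.0)
        y = boltzmann_fraction(V, -45.0, 7.5, "falling")
        fit = fit_boltzmann(np.column_stack([V, y]), "falling")
        assert fit.v_half == pytest.approx(-45.0, abs=1e-4)
        assert fit.k == pytest.approx(7.5, abs=1e-4)

    def test_constant_y_raises(self):
        pts = [(v, 0.5) for v in range(-60, -20, 5)]
        with pytest.raises(FitError, match="degenerate"):
            fit_boltzmann(pts)

    def test_too_few_points_raises(self):
        with pytest.raises(FitError, match=">= 4"):
            fit_boltzmann([(-30, 0.2), (-20, 0.5), (-10, 0.8)])


class TestFitExponential:
    def test_exact_tau(self):
        t = np.array([0.5, 1, 2, 4, 8], dtype=float)
        y = 1 - np.exp(-t / 2.0)
        assert fit_exponential(np.column_stack([t, y])).tau == pytest.approx(2.0, abs=1e-6)

    def test_unit_tau_by_definition(self):
        t = np.array([0.5, 1, 2, 4, 8], dtype=float)
        y = 1 - np.exp(-t)
        assert fit_exponential(np.column_stack([t, y])).tau == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.filterwarnings("ignore:recovery data non-monotone")
    def test_noisy_tau_nearly_unbiased(self):
        """Monte-Carlo: sigma = 0.02 noise on 12 intervals, 200 seeds."""
        rng = np.random.default_rng(20240628)
        t = np.geomspace(0.1, 30, 12)
        taus = []
        for _ in range(200):
            y = 1 - np.exp(-t / 1.19) + rng.normal(0, 0.02, size=t.size)
            taus.append(fit_exponential(np.column_stack([t, y])).tau)
        assert np.mean(taus) == pytest.approx(1.19, rel=0.05)

    def test_non_monotone_warns(self):
        t = np.array([0.5, 1, 2, 4, 8], dtype=float)
        y = 1 - np.exp(-t)
        y[2] -= 0.3
        with pytest.warns(UserWarning, match="non-monotone"):
            fit_exponential(np.column_stack([t, y]))


class TestActivationAnalysis:
    @pytest.mark.parametrize("name, expected", [("WT", -17.56), ("Q1494K", -9.03)])
    def test_half_activation_round_trip(self, library, name, expected):
        params, cond = calibrated_setup(library[name])
        fit = activation_analysis(_run(params, cond, "activation"), cond)
        assert fit.v_half == pytest.approx(expected, abs=1.0)

    def test_slope_recovered_with_instantaneous_activation(self, wt):
        """With near-instant activation and slow inactivation the peak-G curve
        is the steady-state activation curve, so the fitted slope matches."""
        p = wt.with_(tau_act_ms=0.005, tau_inact_ms=50.0, tau_rec_ms=50.0)
        cond = RecordingConditions(g_max_total=20.0)
        fit = activation_analysis(_run(p, cond, "activation"), cond)
        assert fit.k == pytest.approx(p.k_act, rel=0.02)
        assert fit.v_half == pytest.approx(p.v_half_act, abs=0.5)


class TestInactivationAnalysis:
    @pytest.mark.parametrize("name, expected", [("WT", -51.70), ("N1662D", -39.56)])
    def test_half_inactivation_round_trip(self, library, name, expected):
        params, cond = calibrated_setup(library[name])
        fit = inactivation_analysis(_run(params, cond, "inactivation"))
        assert fit.v_half == pytest.approx(expected, abs=1.0)

    def test_zero_floor_synthetic_channel(self, wt):
        p = wt.with_(persistent_frac=0.0, tau_inact_ms=3.0)
        params, = [p]
        cond = RecordingConditions(g_max_total=20.0)
        fit = inactivation_analysis(_run(params, cond, "inactivation"))
        assert fit.v_half == pytest.approx(p.v_half_inact, abs=1.0)


class TestMeasurePersistent:
    def test_wt_calibrated_percent(self, wt):
        params, cond = calibrated_setup(wt)
        res = measure_persistent(_run(params, cond, "persistent"))
        assert not res.nd
        assert res.percent_of_peak == pytest.approx(1.06, abs=0.3)

    def test_non_inactivating_flagged_nd(self, n1662d):
        params, cond = calibrated_setup(n1662d)
        res = measure_persistent(_run(params, cond, "persistent"))
        assert res.nd
        assert res.report_value() == "ND"

    def test_zero_floor_fully_decays(self, wt):
        # availability midpoint moved far from -10 mV so the steady-state
        # tail is negligible and the pure exp(-40/1.5) decay bound applies
        p = wt.with_(persistent_frac=0.0, tau_inact_ms=1.5, v_half_inact=-80.0)
        cond = RecordingConditions(g_max_total=20.0)
        res = measure_persistent(_run(p, cond, "persistent"))
        assert res.percent_of_peak < 0.01

    def test_scale_free_in_conductance(self, wt):
        params, cond = calibrated_setup(wt)
        small = measure_persistent(_run(params, cond, "persistent"))
        big_cond = RecordingConditions(
            c_m=cond.c_m, v_rev=cond.v_rev, g_max_total=cond.g_max_total * 10
        )
        big = measure_persistent(_run(params, big_cond, "persistent"))
        assert big.percent_of_peak == pytest.approx(small.percent_of_peak, rel=1e-9)


class TestRecoveryAnalysis:
    def test_wt_standard_mode(self, wt):
        params, cond = calibrated_setup(wt)
        fit = recovery_analysis(_run(params, cond, "recovery"), mode="standard")
        assert fit.tau == pytest.approx(1.19, rel=0.10)

    def test_l1657p_inactivated_fraction_mode(self, library):
        params, cond = calibrated_setup(library["L1657P"])
        assert default_recovery_mode(params) == "inactivated_fraction"
        fit = recovery_analysis(
            _run(params, cond, "recovery"), mode="inactivated_fraction"
        )
        assert fit.tau == pytest.approx(0.62, rel=0.10)

    def test_unknown_mode_raises(self, wt):
        params, cond = calibrated_setup(wt)
        with pytest.raises(ValueError, match="mode"):
            recovery_analysis(_run(params, cond, "recovery"), mode="banana")


class TestRoundTripIdentifiability:
    """simulate -> analyze recovers the configured gating parameters."""

    @pytest.mark.parametrize("name", ["WT", "N1662D", "Q1494E", "F1651C",
                                      "M1501V", "L1657P", "A1659V"])
    def test_full_characterization(self, library, name):
        p = library[name]
        c = characterize_variant(p)
        assert c.v_half_act == pytest.approx(p.v_half_act, abs=1.0)
        assert c.v_half_inact == pytest.approx(p.v_half_inact, abs=1.0)
        assert c.tau_rec_ms == pytest.approx(p.tau_rec_ms, rel=0.10)
        if not p.non_inactivating:
            assert c.persistent_pct == pytest.approx(100 * p.persistent_frac, abs=0.3)

    @pytest.mark.parametrize("k", [4.0, 9.0])
    def test_insensitive_to_slope_factor(self, wt, k):
        p = wt.with_(k_act=k, k_inact=k)
        c = characterize_variant(p)
        assert c.v_half_act == pytest.approx(p.v_half_act, abs=1.0)
        assert c.v_half_inact == pytest.approx(p.v_half_inact, abs=1.0)
        assert c.tau_rec_ms == pytest.approx(p.tau_rec_ms, rel=0.10)

    def test_dt_halving_stability(self, wt):
        coarse = characterize_variant(wt, dt=0.02)
        fine = characterize_variant(wt, dt=0.01)
        for attr in ("v_half_act", "v_half_inact", "tau_rec_ms", "persistent_pct"):
            a, b = getattr(coarse, attr), getattr(fine, attr)
            assert b == pytest.approx(a, rel=1e-3)


def test_conductance_transform_inverts_channel_current(wt):
    """Peak G at strong depolarization equals g_max x h there (within 1%)
    when activation is effectively instantaneous."""
    p = wt.with_(tau_act_ms=0.005, tau_inact_ms=50.0, tau_rec_ms=50.0)
    cond = RecordingConditions(g_max_total=20.0)
    traces = _run(p, cond, "activation")
    from navclamp.clamp import peak_inward

    i30 = list(traces.protocol.sweep_values).index(30.0)
    peak = peak_inward(traces, i30, "step")
    g = peak / (30.0 - cond.v_rev)
    assert g == pytest.approx(cond.g_max_total, rel=0.01)
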