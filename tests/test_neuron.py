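"""Hybrid AIS neuron: passive oracles, spike detection, conservation, and
basic dynamic-clamp behaviour."""

import numpy as np
import pytest

from navclamp.neuron import (
    AISModel,
    DAPCConfig,
    check_current_balance,
    detect_spikes,
    detect_sustained_depolarization,
    input_output_curve,
    pearson_r,
    run_hybrid_sim,
)


@pytest.fixture(scope="module")
def ais():
    return AISModel()


@pytest.fixture(scope="module")
def passive():
    """Leak-only membrane (all active conductances zero)."""
    return AISModel(gKv_scale=0.0, gNav16_scale=0.0)


def short_config(variant, frac=0.0, dur=200.0, amps=(0.0,)):
    return DAPCConfig(variant=variant, na12_fraction=frac,
                      stim_dur_ms=dur, stim_amplitudes_pA=tuple(amps))


class TestPassiveMembrane:
    def test_rest_at_leak_reversal_without_stimulus(self, passive, wt):
        res = run_hybrid_sim(passive, short_config(wt), 0.0)
        assert np.allclose(res.vm_mV, passive.e_leak, atol=1e-6)

    def test_step_response_matches_rc_closed_form(self, passive, wt):
        """V(t) = e_leak + (I/g)(1 - exp(-t g/c)) pointwise to < 0.1 mV."""
        amp = 10.0
        res = run_hybrid_sim(passive, short_config(wt, dur=300.0), amp)
        tau = passive.c_m / passive.g_leak
        t = res.time_ms
        on = res.stim_start_ms
        expected = np.where(
            t < on,
            passive.e_leak,
            passive.e_leak + (amp / passive.g_leak) * (1 - np.exp(-(t - on) / tau)),
        )
        inside = (t >= on) & (t < on + 300.0)
        assert np.max(np.abs(res.vm_mV[inside] - expected[inside])) < 0.1


class TestRestingState:
    def test_rest_between_minus80_and_minus60(self, ais, wt):
        res = run_hybrid_sim(ais, short_config(wt), 0.0)
        assert -80.0 < res.vm_mV[-1] < -60.0
        # stationary: no drift over the episode
        assert abs(res.vm_mV[-1] - res.vm_mV[len(res.vm_mV) // 2]) < 0.5


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 100, 0.02)
        assert len(detect_spikes(t, np.full_like(t, -70.0))) == 0

    def test_single_crossing_is_one_spike(self):
        t = np.arange(0, 10, 0.02)
        vm = np.full_like(t, -70.0)
        vm[(t > 4) & (t < 5)] = 20.0
        assert len(detect_spikes(t, vm)) == 1

    def test_forty_hz_train_counts_forty(self):
        t = np.arange(0, 1000, 0.02)
        vm = np.full_like(t, -70.0)
        for k in range(40):  # 1-ms square pulses every 25 ms
            vm[(t >= 25 * k + 5) & (t < 25 * k + 6)] = 10.0
        spikes = detect_spikes(t, vm)
        assert len(spikes) == 40

    def test_refractory_merges_fast_double_crossings(self):
        t = np.arange(0, 10, 0.02)
        vm = np.full_like(t, -70.0)
        vm[(t > 4.0) & (t < 4.3)] = 10.0
        vm[(t > 4.6) & (t < 4.9)] = 10.0  # 0.6 ms later: within refractory
        assert len(detect_spikes(t, vm)) == 1


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 5.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestConservation:
    def test_current_balance_residual_small_and_converging(self, ais, wt):
        cfg = short_config(wt, dur=300.0)
        res = run_hybrid_sim(ais, cfg, 10.0)
        scale = max(np.abs(np.column_stack(
            [res.i_kv, res.i_nav16, res.i_leak, res.i_stim])).max(), 1.0)
        resid = check_current_balance(res)
        assert resid < 0.08 * scale
        cfg_fine = DAPCConfig(variant=wt, na12_fraction=0.0,
                              stim_dur_ms=300.0, dt_ms=0.01)
        resid_fine = check_current_balance(run_hybrid_sim(ais, cfg_fine, 10.0))
        assert resid_fine < 0.6 * resid  # second-order in dt


class TestFiring:
    def test_stimulus_family_has_14_amplitudes(self, wt):
        cfg = DAPCConfig(variant=wt, na12_fraction=0.0)
        assert len(cfg.stim_amplitudes_pA) == 14
        assert cfg.stim_amplitudes_pA[0] == -2.0
        assert cfg.stim_amplitudes_pA[-1] == 24.0

    def test_passive_membrane_never_fires(self, passive, wt):
        cfg = DAPCConfig(variant=wt, na12_fraction=0.0, stim_dur_ms=400.0,
                         stim_amplitudes_pA=(0.0, 12.0, 24.0))
        summary = input_output_curve(passive, cfg)
        assert np.all(summary.mean_freq_hz == 0.0)

    def test_suprathreshold_step_fires_repetitively(self, ais, wt):
        cfg = DAPCConfig(variant=wt, na12_fraction=0.0)
        res = run_hybrid_sim(ais, cfg, 10.0)
        spikes = detect_spikes(res.time_ms, res.vm_mV)
        assert len(spikes) >= 5

    def test_dt_halving_preserves_spike_count_and_plateau(self, ais, wt, n1662d):
        cfg = DAPCConfig(variant=wt, na12_fraction=0.0, dt_ms=0.02)
        cfg2 = DAPCConfig(variant=wt, na12_fraction=0.0, dt_ms=0.01)
        s1 = detect_spikes(*_vm(run_hybrid_sim(ais, cfg, 10.0)))
        s2 = detect_spikes(*_vm(run_hybrid_sim(ais, cfg2, 10.0)))
        assert len(s1) == len(s2)
        a0 = ais.with_(gNav16_scale=0.0)
        p1 = detect_sustained_depolarization(
            run_hybrid_sim(a0, DAPCConfig(variant=n1662d, na12_fraction=0.2), 12.0))
        p2 = detect_sustained_depolarization(
            run_hybrid_sim(a0, DAPCConfig(variant=n1662d, na12_fraction=0.2, dt_ms=0.01), 12.0))
        assert p1.sustained and p2.sustained
        assert abs(p1.plateau_vm - p2.plateau_vm) < 0.5


def _vm(res):
    return res.time_ms, res.vm_mV


class TestSustainedDepolarization:
    def test_resting_trace_not_sustained(self, ais, wt):
        res = run_hybrid_sim(ais, DAPCConfig(variant=wt, na12_fraction=0.0), 0.0)
        assert not detect_sustained_depolarization(res).sustained

    def test_tonic_firing_not_sustained(self, ais, wt):
        res = run_hybrid_sim(ais, DAPCConfig(variant=wt, na12_fraction=0.0), 10.0)
        assert not detect_sustained_depolarization(res).sustained

    def test_invalid_fraction_rejected(self, wt):
        with pytest.raises(ValueError, match="fraction"):
            DAPCConfig(variant=wt, na12_fraction=-0.1)
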