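"""Single-cell and synapse dynamics: resting stability, firing phenotypes,
numerical convergence, and the first-order / two-stage synapse schemes."""
import dataclasses
import math

import numpy as np
import pytest

from alnet.cells import (
    GatingState, MembraneParams, SlowInhibitionState, SynapticKinetics,
    detect_spikes, fi_curve, simulate_neuron, slow_inhibition_drive,
    step_neuron, step_slow_inhibition, steady_gates, synaptic_drive,
)

DT = 0.04


def _run_dc(params, i_nA, dur_ms, dt=DT, settle=True):
    state = GatingState.resting(params) if settle else None
    if state is not None:
        state = dataclasses.replace(state, gates=state.gates.copy())
    v, ca = simulate_neuron(params, np.full(int(dur_ms / dt), i_nA), dt=dt,
                            state=state)
    return v, detect_spikes(v, dt, params)


class TestMembrane:
    def test_pn_rest_is_stable(self, pn_params):
        v, spikes = _run_dc(pn_params, 0.0, 500.0, settle=False)
        assert len(spikes) == 0
        assert np.all(np.abs(v - v[-1]) < 2.0)

    def test_ln_rest_is_stable(self, ln_params):
        v, spikes = _run_dc(ln_params, 0.0, 500.0, settle=False)
        assert len(spikes) == 0
        assert np.all(np.abs(v - v[-1]) < 3.0)

    def test_eln_equals_pn(self, pn_params, eln_params):
        assert eln_params.channels == pn_params.channels
        assert eln_params.capacitance_uF == pn_params.capacitance_uF
        assert eln_params.g_leak_uS == pn_params.g_leak_uS

    def test_pn_tonic_overshooting_spikes(self, pn_params):
        """Suprathreshold DC: overshooting Na spikes at fixed frequency."""
        v, spikes = _run_dc(pn_params, 0.03, 2000.0)
        assert v.max() > 0.0, "PN spikes must overshoot 0 mV"
        isi = np.diff(spikes)
        assert len(isi) >= 6
        tail = isi[3:]
        assert tail.std() / tail.mean() < 0.05

    def test_pn_fi_curve_monotone(self, pn_params):
        rates = fi_curve(pn_params, np.linspace(0.02, 0.06, 5),
                         duration_ms=800.0)
        assert np.all(np.diff(rates) >= 0)
        assert rates[-1] > 0

    @pytest.mark.parametrize("i_dc", [0.02, 0.028])
    def test_ln_low_amplitude_adapting_spikes(self, ln_params, i_dc):
        """DC drive: Ca spikes peak below 0 mV with growing ISIs."""
        v, spikes = _run_dc(ln_params, i_dc, 2000.0)
        assert len(spikes) >= 5
        assert v.max() < 0.0, "LN events are low-amplitude (below 0 mV)"
        isi = np.diff(spikes)[:4]
        assert np.all(np.diff(isi) >= 0)
        assert isi[-1] > isi[0]

    def test_ln_adaptation_index(self, ln_params):
        """Last ISI over first ISI under 1 s of DC exceeds 1."""
        _, spikes = _run_dc(ln_params, 0.028, 1000.0)
        isi = np.diff(spikes)
        assert len(isi) >= 2
        assert isi[-1] / isi[0] > 1.0

    def test_step_halving_convergence(self, pn_params):
        """Halving dt from 0.04 to 0.02 ms moves spike times < 1 ms."""
        times = {}
        for dt in (0.04, 0.02):
            v, _ = simulate_neuron(pn_params, np.full(int(1000 / dt), 0.03),
                                   dt=dt)
            times[dt] = detect_spikes(v, dt, pn_params)
        n = min(len(times[0.04]), len(times[0.02]))
        assert n > 5
        assert abs(len(times[0.04]) - len(times[0.02])) <= 1
        assert np.max(np.abs(times[0.04][:n] - times[0.02][:n])) < 1.0

    def test_gates_bounded_under_random_input(self, pn_params, ln_params, rng):
        """Gating stays in [0,1] and calcium >= 0 for bounded noisy drive."""
        for params in (pn_params, ln_params):
            state = GatingState(params.E_leak_mV,
                                steady_gates(params, params.E_leak_mV),
                                params.ca_rest)
            for _ in range(2000):
                state = step_neuron(state, params,
                                    float(rng.uniform(-0.05, 0.08)), DT)
            state.validate()

    def test_step_neuron_rejects_bad_input(self, pn_params):
        state = GatingState(pn_params.E_leak_mV,
                            steady_gates(pn_params, pn_params.E_leak_mV))
        with pytest.raises(ValueError, match="input_current_nA"):
            step_neuron(state, pn_params, float("nan"), DT)
        with pytest.raises(ValueError, match="dt"):
            step_neuron(state, pn_params, 0.0, 0.5)
        bad = GatingState(float("inf"), steady_gates(pn_params, -65.0))
        with pytest.raises(ValueError, match="voltage"):
            step_neuron(bad, pn_params, 0.0, DT)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MembraneParams("PN", capacitance_uF=-1.0, g_leak_uS=0.01,
                           E_leak_mV=-65.0, channels={})
        with pytest.raises(ValueError):
            MembraneParams("XX", capacitance_uF=1.0, g_leak_uS=0.01,
                           E_leak_mV=-65.0, channels={})


class TestFastSynapse:
    def _square_presyn(self, on_ms, total_ms, dt=DT, v_high=20.0):
        v = np.full(int(total_ms / dt), -65.0)
        v[: int(on_ms / dt)] = v_high
        return v

    def test_silent_presyn_gives_zero(self):
        kin = SynapticKinetics.default("nACh", g_max_uS=0.5)
        v = np.full(5000, -65.0)
        assert np.all(synaptic_drive(kin, v, DT) == 0)

    @pytest.mark.parametrize("cls", ["nACh", "GABA_A"])
    def test_single_pulse_area_matches_closed_form(self, cls):
        """Conductance time-integral equals the analytic solution."""
        kin = SynapticKinetics.default(cls, g_max_uS=1.0)
        d = 2.0    # release duration, ms
        v = self._square_presyn(d, 400.0)
        g = synaptic_drive(kin, v, DT)
        a, b = kin.alpha_per_ms, kin.beta_per_ms
        s_inf = a / (a + b)
        s_end = s_inf * (1.0 - math.exp(-(a + b) * d))
        area_on = s_inf * (d - (1.0 - math.exp(-(a + b) * d)) / (a + b))
        area = area_on + s_end / b
        assert g.max() <= kin.g_max_uS
        assert np.all(g >= 0)
        assert g.sum() * DT == pytest.approx(area, rel=0.01)

    def test_paired_pulses_summate(self):
        kin = SynapticKinetics.default("nACh", g_max_uS=1.0)
        dt = DT
        v = np.full(int(60 / dt), -65.0)
        for t0 in (0.0, 3.0):
            v[int(t0 / dt): int((t0 + 1.0) / dt)] = 20.0
        g = synaptic_drive(kin, v, dt)
        peak1 = g[: int(3 / dt)].max()
        peak2 = g[int(3 / dt):].max()
        assert peak2 > peak1

    def test_decay_to_zero(self):
        kin = SynapticKinetics.default("GABA_A", g_max_uS=1.0)
        g = synaptic_drive(kin, self._square_presyn(1.0, 500.0), DT)
        assert g[-1] < 1e-6

    def test_negative_gmax_rejected(self):
        with pytest.raises(ValueError):
            SynapticKinetics.default("nACh", g_max_uS=-1.0)


class TestSlowInhibition:
    def test_no_activity_zero_conductance(self):
        active = np.zeros(10000, dtype=bool)
        g = slow_inhibition_drive(active, DT)
        assert np.all(g == 0)

    def test_burst_response_slower_than_gaba_a(self):
        """GABA_B peaks later and decays slower than GABA_A for one burst."""
        dt = 0.1
        n = int(2000 / dt)
        active = np.zeros(n, dtype=bool)
        active[: int(50 / dt)] = True     # 50 ms burst
        g_b = slow_inhibition_drive(active, dt)
        kin_a = SynapticKinetics.default("GABA_A", g_max_uS=1.0)
        v = np.where(active, 20.0, -65.0)
        g_a = synaptic_drive(kin_a, v, dt)
        t_peak_b = np.argmax(g_b) * dt
        t_peak_a = np.argmax(g_a) * dt
        assert t_peak_b > t_peak_a
        # time from the GABA_B peak to half amplitude exceeds 100 ms
        k_peak = np.argmax(g_b)
        below = np.flatnonzero(g_b[k_peak:] < 0.5 * g_b[k_peak])
        assert len(below) == 0 or below[0] * dt > 100.0

    def test_sustained_activity_saturates_at_fixed_point(self):
        """Plateau equals the analytic fixed point of the two-stage scheme."""
        from alnet.params import default_params
        kin = default_params()["synapses"]["GABA_B"]
        dt = 0.1
        active = np.ones(int(60000 / dt), dtype=bool)
        g = slow_inhibition_drive(active, dt, g_max_uS=1.0, kinetics=kin)
        r_star = kin["K1_per_ms"] / (kin["K1_per_ms"] + kin["K2_per_ms"])
        s_star = kin["K3_per_ms"] * r_star / kin["K4_per_ms"]
        g_star = s_star ** kin["hill"] / (s_star ** kin["hill"] + kin["Kd"])
        assert g[-1] == pytest.approx(g_star, rel=0.01)
        assert np.all(np.diff(g[-1000:]) < 1e-9)   # plateaued

    def test_state_invariants(self):
        state = SlowInhibitionState()
        for _ in range(5000):
            state, g = step_slow_inhibition(state, True, 0.1)
            assert 0.0 <= state.bound <= 1.0
            assert state.effector >= 0.0
            assert g >= 0.0
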