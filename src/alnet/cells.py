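"""Single-compartment conductance-based models of antennal-lobe neurons.

Three cell classes are modeled with Hodgkin–Huxley-type kinetics:

* **PN** — projection neurons: transient Na, delayed-rectifier K, transient
  A-type K and leak. They fire overshooting Na spikes at a fixed rate under
  DC stimulation.
* **eLN** — excitatory local interneurons, biophysically identical to PNs.
* **LN** — inhibitory local interneurons: low-threshold Ca, Ca-dependent K,
  delayed-rectifier K, leak and a first-order intracellular Ca pool. They
  fire low-amplitude Ca spikes and adapt through the Ca-dependent K current.

Synapses (fast GABA_A, nicotinic ACh) follow a first-order activation
scheme gated by presynaptic voltage crossing a release threshold. Slow
GABA_B inhibition uses a two-stage receptor → G-protein scheme with a
Hill-type conductance nonlinearity, which integrates presynaptic activity
over hundreds of milliseconds.

Units: voltage mV, time ms, conductance µS, current nA, capacitance µF
(so dV/dt = 1e-3 · I[nA] / C[µF] in mV/ms).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
from numba import njit

from .params import default_params

__all__ = [
    "MembraneParams", "GatingState", "SynapticKinetics", "SlowInhibitionState",
    "step_neuron", "simulate_neuron", "synaptic_drive", "step_slow_inhibition",
    "slow_inhibition_drive", "detect_spikes", "fi_curve",
]

_N_GATES = {"PN": 5, "eLN": 5, "LN": 4}  # PN: m,h,n,a,b — LN: mCa,hCa,q,nK


# --------------------------------------------------------------------------
# parameter / state containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneParams:
    """Membrane constants for one cell class.

    ``channels`` maps channel name to ``{"g_uS": ..., "E_mV": ...}`` records
    (plus kinetic shifts where applicable).
    """
    cell_class: str
    capacitance_uF: float
    g_leak_uS: float
    E_leak_mV: float
    channels: dict[str, dict[str, float]]
    ca_tau_ms: float | None = None
    ca_rest: float = 0.0
    ca_influx_per_nA_ms: float = 0.0
    spike_mode: str = "threshold_crossing"
    spike_threshold_mV: float = 0.0
    spike_refractory_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.cell_class not in _N_GATES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.capacitance_uF <= 0:
            raise ValueError("capacitance must be > 0")
        if self.g_leak_uS < 0:
            raise ValueError("leak conductance must be >= 0")
        for name, rec in self.channels.items():
            if rec["g_uS"] < 0:
                raise ValueError(f"channel {name}: conductance must be >= 0")

    @classmethod
    def from_dict(cls, cell_class: str, rec: dict[str, Any]) -> "MembraneParams":
        pool = rec.get("ca_pool")
        return cls(
            cell_class=cell_class,
            capacitance_uF=rec["capacitance_uF"],
            g_leak_uS=rec["leak"]["g_uS"],
            E_leak_mV=rec["leak"]["E_mV"],
            channels=rec["channels"],
            ca_tau_ms=None if pool is None else pool["tau_ms"],
            ca_rest=0.0 if pool is None else pool["rest"],
            ca_influx_per_nA_ms=0.0 if pool is None else pool["influx_per_nA_ms"],
            spike_mode=rec["spike"]["mode"],
            spike_threshold_mV=rec["spike"]["threshold_mV"],
            spike_refractory_ms=rec["spike"].get("refractory_ms", 2.0),
        )

    @classmethod
    def default(cls, cell_class: str) -> "MembraneParams":
        return cls.from_dict(cell_class, default_params()["cells"][cell_class])

    def as_array(self) -> np.ndarray:
        """Flat float64 layout consumed by the integration kernels."""
        ch = self.channels
        if self.cell_class in ("PN", "eLN"):
            return np.array([
                self.capacitance_uF, self.g_leak_uS, self.E_leak_mV,
                ch["Na"]["g_uS"], ch["Na"]["E_mV"], ch["Na"]["VT_mV"],
                ch["K"]["g_uS"], ch["K"]["E_mV"],
                ch["KA"]["g_uS"], ch["KA"]["E_mV"],
            ])
        return np.array([
            self.capacitance_uF, self.g_leak_uS, self.E_leak_mV,
            ch["CaT"]["g_uS"], ch["CaT"]["E_mV"],
            ch["KCa"]["g_uS"], ch["KCa"]["E_mV"],
            ch["K"]["g_uS"], ch["K"]["E_mV"], ch["K"]["VT_mV"],
            self.ca_tau_ms, self.ca_rest, self.ca_influx_per_nA_ms,
        ])


@dataclass
class GatingState:
    """Voltage, channel gating variables and intracellular calcium."""
    voltage_mV: float
    gates: np.ndarray          # per-class order, each in [0, 1]
    calcium: float = 0.0

    def validate(self) -> None:
        if not np.isfinite(self.voltage_mV):
            raise ValueError("non-finite state variable: voltage_mV")
        if not np.all(np.isfinite(self.gates)):
            bad = int(np.flatnonzero(~np.isfinite(self.gates))[0])
            raise ValueError(f"non-finite state variable: gates[{bad}]")
        if not np.isfinite(self.calcium):
            raise ValueError("non-finite state variable: calcium")
        if np.any(self.gates < 0) or np.any(self.gates > 1):
            raise ValueError("gating variables must lie in [0, 1]")
        if self.calcium < 0:
            raise ValueError("calcium must be >= 0")

    @classmethod
    def resting(cls, params: MembraneParams) -> "GatingState":
        """Approximate resting state: settle the cell with zero input."""
        state = cls(voltage_mV=params.E_leak_mV,
                    gates=np.zeros(_N_GATES[params.cell_class]),
                    calcium=params.ca_rest)
        v, ca, g = simulate_neuron(params, np.zeros(int(500 / 0.04)), dt=0.04,
                                   state=state, return_final=True)
        return g


@dataclass(frozen=True)
class SynapticKinetics:
    """First-order synapse: ds/dt = α·T·(1−s) − β·s with T ∈ {0, 1}."""
    synapse_class: str
    alpha_per_ms: float
    beta_per_ms: float
    E_mV: float
    g_max_uS: float
    release_threshold_mV: float = -20.0

    def __post_init__(self) -> None:
        if self.alpha_per_ms <= 0 or self.beta_per_ms <= 0:
            raise ValueError("rate constants must be > 0")
        if self.g_max_uS < 0:
            raise ValueError("maximal conductance must be >= 0")
        if self.synapse_class in ("GABA_A", "GABA_B") and self.E_mV > -70:
            raise ValueError("inhibitory reversal must be <= -70 mV")
        if self.synapse_class == "nACh" and self.E_mV < 0:
            raise ValueError("nACh reversal must be >= 0 mV")

    @classmethod
    def default(cls, synapse_class: str, g_max_uS: float = 1.0) -> "SynapticKinetics":
        rec = default_params()["synapses"][synapse_class]
        if synapse_class == "GABA_B":
            # expose forward/backward rates of the first (receptor) stage
            return cls(synapse_class, rec["K1_per_ms"], rec["K2_per_ms"],
                       rec["E_mV"], g_max_uS, rec["release_threshold_mV"])
        return cls(synapse_class, rec["alpha_per_ms"], rec["beta_per_ms"],
                   rec["E_mV"], g_max_uS, rec["release_threshold_mV"])


@dataclass
class SlowInhibitionState:
    """Two-stage GABA_B state: bound receptor fraction and G-protein level."""
    bound: float = 0.0      # r in [0, 1]
    effector: float = 0.0   # s >= 0

    def validate(self) -> None:
        if not (0.0 <= self.bound <= 1.0):
            raise ValueError("bound-receptor fraction must lie in [0, 1]")
        if not (self.effector >= 0.0):
            raise ValueError("effector concentration must be >= 0")


# --------------------------------------------------------------------------
# rate functions (scalar, numba-compiled; shared with the network kernel)
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _linoid(x):
    """x / (1 - exp(-x)), continuous at 0."""
    if abs(x) < 1e-6:
        return 1.0 + 0.5 * x
    return x / (1.0 - math.exp(-x))


@njit(cache=True, fastmath=True)
def _pn_rates(v, vt):
    """Traub–Miles Na/K rates (ms^-1) shifted by the spike-threshold offset."""
    u = v - vt
    am = 1.28 * _linoid((u - 13.0) / 4.0)
    bm = 1.4 * _linoid(-(u - 40.0) / 5.0)
    ah = 0.128 * math.exp(-(u - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(u - 40.0) / 5.0))
    an = 0.16 * _linoid((u - 15.0) / 5.0)
    bn = 0.5 * math.exp(-(u - 10.0) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True, fastmath=True)
def _ka_gates(v):
    """Transient A-type K: steady states and time constants (Huguenard-type)."""
    a_inf = 1.0 / (1.0 + math.exp(-(v + 60.0) / 8.5))
    tau_a = 0.37 + 1.0 / (math.exp((v + 35.8) / 19.7) + math.exp(-(v + 79.7) / 12.7))
    b_inf = 1.0 / (1.0 + math.exp((v + 78.0) / 6.0))
    if v < -63.0:
        tau_b = 1.0 / (math.exp((v + 46.0) / 5.0) + math.exp(-(v + 238.0) / 37.5))
    else:
        tau_b = 19.0
    return a_inf, tau_a, b_inf, tau_b


@njit(cache=True, fastmath=True)
def _ln_ca_gates(v):
    """Low-threshold Ca current: activation/inactivation steady states."""
    m_inf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 7.0))
    h_inf = 0.2 + 0.8 / (1.0 + math.exp((v + 35.0) / 12.0))
    return m_inf, 1.0, h_inf, 500.0


@njit(cache=True, fastmath=True)
def _clamp01(x):
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True, fastmath=True)
def _step_pn_scalar(v, m, h, n, a, b, i_nA, dt, par):
    cm, gl, el = par[0], par[1], par[2]
    gna, ena, vt = par[3], par[4], par[5]
    gk, ek = par[6], par[7]
    gka, eka = par[8], par[9]
    am, bm, ah, bh, an, bn = _pn_rates(v, vt)
    m = am / (am + bm) + (m - am / (am + bm)) * math.exp(-dt * (am + bm))
    h = ah / (ah + bh) + (h - ah / (ah + bh)) * math.exp(-dt * (ah + bh))
    n = an / (an + bn) + (n - an / (an + bn)) * math.exp(-dt * (an + bn))
    a_inf, tau_a, b_inf, tau_b = _ka_gates(v)
    a = a_inf + (a - a_inf) * math.exp(-dt / tau_a)
    b = b_inf + (b - b_inf) * math.exp(-dt / tau_b)
    m, h, n = _clamp01(m), _clamp01(h), _clamp01(n)
    a, b = _clamp01(a), _clamp01(b)
    # exponential-Euler voltage update (accurate through the stiff upstroke)
    g_na = gna * m * m * m * h
    g_k = gk * n * n * n * n
    g_ka = gka * a * a * a * a * b
    g_tot = gl + g_na + g_k + g_ka
    v_inf = (gl * el + g_na * ena + g_k * ek + g_ka * eka + i_nA) / g_tot
    v = v_inf + (v - v_inf) * math.exp(-dt * g_tot * 1e-3 / cm)
    return v, m, h, n, a, b


@njit(cache=True, fastmath=True)
def _step_ln_scalar(v, mc, hc, q, nk, ca, i_nA, dt, par):
    cm, gl, el = par[0], par[1], par[2]
    gca, eca = par[3], par[4]
    gkca, ekca = par[5], par[6]
    gk, ek, vt = par[7], par[8], par[9]
    ca_tau, ca_rest, ca_influx = par[10], par[11], par[12]
    mc_inf, tau_mc, hc_inf, tau_hc = _ln_ca_gates(v)
    mc = mc_inf + (mc - mc_inf) * math.exp(-dt / tau_mc)
    hc = hc_inf + (hc - hc_inf) * math.exp(-dt / tau_hc)
    # recovery gate: sigmoidal steady state, voltage-dependent time constant
    w_inf = 1.0 / (1.0 + math.exp(-(v - vt - 30.0) / 5.0))
    tau_w = 6.0 / math.cosh((v - vt - 30.0) / 30.0)
    nk = w_inf + (nk - w_inf) * math.exp(-dt / tau_w)
    q_inf = ca * ca / (ca * ca + 4.0)
    q = q_inf + (q - q_inf) * math.exp(-dt / 50.0)
    mc, hc, q, nk = _clamp01(mc), _clamp01(hc), _clamp01(q), _clamp01(nk)
    g_ca = gca * mc * mc * hc
    g_kca = gkca * q
    g_k = gk * nk * nk
    i_ca = g_ca * (v - eca)                    # negative = inward
    ca = ca + dt * (-ca_influx * i_ca - (ca - ca_rest) / ca_tau)
    if ca < 0.0:
        ca = 0.0
    g_tot = gl + g_ca + g_kca + g_k
    v_inf = (gl * el + g_ca * eca + g_kca * ekca + g_k * ek + i_nA) / g_tot
    v = v_inf + (v - v_inf) * math.exp(-dt * g_tot * 1e-3 / cm)
    return v, mc, hc, q, nk, ca


@njit(cache=True, fastmath=True)
def _run_pn(par, i_trace, dt, v0, g0):
    nt = i_trace.shape[0]
    out = np.empty(nt)
    v, m, h, n, a, b = v0, g0[0], g0[1], g0[2], g0[3], g0[4]
    for k in range(nt):
        v, m, h, n, a, b = _step_pn_scalar(v, m, h, n, a, b, i_trace[k], dt, par)
        out[k] = v
    return out, np.array([m, h, n, a, b]), 0.0


@njit(cache=True, fastmath=True)
def _run_ln(par, i_trace, dt, v0, g0, ca0):
    nt = i_trace.shape[0]
    out = np.empty(nt)
    ca_out = np.empty(nt)
    v, mc, hc, q, nk, ca = v0, g0[0], g0[1], g0[2], g0[3], ca0
    for k in range(nt):
        v, mc, hc, q, nk, ca = _step_ln_scalar(v, mc, hc, q, nk, ca,
                                               i_trace[k], dt, par)
        out[k] = v
        ca_out[k] = ca
    return out, ca_out, np.array([mc, hc, q, nk])


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def steady_gates(params: MembraneParams, v: float) -> np.ndarray:
    """Gating variables at their voltage-clamped steady state."""
    if params.cell_class in ("PN", "eLN"):
        vt = params.channels["Na"]["VT_mV"]
        am, bm, ah, bh, an, bn = _pn_rates(v, vt)
        a_inf, _, b_inf, _ = _ka_gates(v)
        return np.array([am / (am + bm), ah / (ah + bh), an / (an + bn),
                         a_inf, b_inf])
    vt = params.channels["K"]["VT_mV"]
    mc_inf, _, hc_inf, _ = _ln_ca_gates(v)
    w_inf = 1.0 / (1.0 + math.exp(-(v - vt - 30.0) / 5.0))
    ca = params.ca_rest
    q_inf = ca * ca / (ca * ca + 4.0)
    return np.array([mc_inf, hc_inf, q_inf, w_inf])


def step_neuron(state: GatingState, params: MembraneParams,
                input_current_nA: float, dt: float) -> GatingState:
    """Advance one neuron by a single time step of length ``dt``.

    Gating variables use exponential (Rush–Larsen) updates; the voltage uses
    forward Euler. Deterministic given its inputs.
    """
    if not (0 < dt <= 0.1):
        raise ValueError("dt must lie in (0, 0.1] ms")
    state.validate()
    if not np.isfinite(input_current_nA):
        raise ValueError("non-finite input: input_current_nA")
    par = params.as_array()
    g = state.gates
    if params.cell_class in ("PN", "eLN"):
        v, m, h, n, a, b = _step_pn_scalar(
            state.voltage_mV, g[0], g[1], g[2], g[3], g[4],
            input_current_nA, dt, par)
        return GatingState(v, np.array([m, h, n, a, b]), 0.0)
    v, mc, hc, q, nk, ca = _step_ln_scalar(
        state.voltage_mV, g[0], g[1], g[2], g[3], state.calcium,
        input_current_nA, dt, par)
    return GatingState(v, np.array([mc, hc, q, nk]), ca)


def simulate_neuron(params: MembraneParams, current_nA: np.ndarray,
                    dt: float = 0.04, state: GatingState | None = None,
                    return_final: bool = False):
    """Integrate one neuron over a full current trace.

    Returns ``(voltage_trace, calcium_trace)``; with ``return_final=True``
    additionally returns the final :class:`GatingState`.
    """
    if not (0 < dt <= 0.1):
        raise ValueError("dt must lie in (0, 0.1] ms")
    current_nA = np.asarray(current_nA, dtype=np.float64)
    if not np.all(np.isfinite(current_nA)):
        raise ValueError("non-finite input: current_nA")
    if state is None:
        state = GatingState(params.E_leak_mV,
                            steady_gates(params, params.E_leak_mV),
                            params.ca_rest)
    state.validate()
    par = params.as_array()
    if params.cell_class in ("PN", "eLN"):
        v, gates, _ = _run_pn(par, current_nA, dt,
                              state.voltage_mV, state.gates)
        ca_trace = np.zeros_like(v)
        ca_final = 0.0
    else:
        v, ca_trace, gates = _run_ln(par, current_nA, dt,
                                     state.voltage_mV, state.gates,
                                     state.calcium)
        ca_final = float(ca_trace[-1]) if len(ca_trace) else state.calcium
    v_final = float(v[-1]) if len(v) else state.voltage_mV
    if return_final:
        return v, ca_trace, GatingState(v_final, gates, ca_final)
    return v, ca_trace


def detect_spikes(voltage_mV: np.ndarray, dt: float,
                  params: MembraneParams) -> np.ndarray:
    """Spike times (ms) for a voltage trace.

    PN/eLN spikes are upward crossings of 0 mV (overshooting Na spikes);
    LN events are local maxima above −20 mV separated by a ≥ 5 ms
    refractory interval (low-amplitude Ca spikes).
    """
    v = np.asarray(voltage_mV)
    if params.spike_mode == "threshold_crossing":
        thr = params.spike_threshold_mV
        idx = np.flatnonzero((v[:-1] < thr) & (v[1:] >= thr)) + 1
        return idx * dt
    thr = params.spike_threshold_mV
    cand = np.flatnonzero((v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:])
                          & (v[1:-1] > thr)) + 1
    times = []
    last = -np.inf
    refr = params.spike_refractory_ms
    for i in cand:
        t = i * dt
        if t - last >= refr:
            times.append(t)
            last = t
    return np.asarray(times)


def fi_curve(params: MembraneParams, currents_nA: np.ndarray,
             duration_ms: float = 1000.0, dt: float = 0.04) -> np.ndarray:
    """Firing rate (spikes/s) under DC stimulation, per current value."""
    rates = np.empty(len(currents_nA))
    nt = int(round(duration_ms / dt))
    for k, i0 in enumerate(currents_nA):
        v, _ = simulate_neuron(params, np.full(nt, i0), dt=dt)
        rates[k] = len(detect_spikes(v, dt, params)) / (duration_ms / 1000.0)
    return rates


def synaptic_drive(kin: SynapticKinetics, presyn_voltage_mV: np.ndarray,
                   dt: float) -> np.ndarray:
    """Conductance trace (µS) of a first-order synapse driven by a
    presynaptic voltage trace.

    Transmitter is released (T = 1) while the presynaptic voltage exceeds
    the release threshold; the gating variable then relaxes exponentially,
    so the conductance is bounded by ``g_max_uS`` and decays to zero in the
    absence of activity.
    """
    if kin.g_max_uS < 0:
        raise ValueError("maximal conductance must be >= 0")
    v = np.asarray(presyn_voltage_mV, dtype=np.float64)
    active = v > kin.release_threshold_mV
    s = 0.0
    out = np.empty(len(v))
    a, b = kin.alpha_per_ms, kin.beta_per_ms
    e_on = math.exp(-dt * (a + b))
    e_off = math.exp(-dt * b)
    s_inf = a / (a + b)
    for k in range(len(v)):
        if active[k]:
            s = s_inf + (s - s_inf) * e_on
        else:
            s = s * e_off
        out[k] = s
    return kin.g_max_uS * out


def step_slow_inhibition(state: SlowInhibitionState, presyn_active: bool,
                         dt: float, g_max_uS: float = 1.0,
                         kinetics: dict | None = None
                         ) -> tuple[SlowInhibitionState, float]:
    """Advance the two-stage GABA_B scheme by one step.

    Stage 1: transmitter binds receptors, dr/dt = K1·T·(1−r) − K2·r.
    Stage 2: bound receptors activate G protein, ds/dt = K3·r − K4·s.
    Conductance: g = g_max · s⁴ / (s⁴ + Kd), a saturating Hill nonlinearity
    that makes the conductance integrate presynaptic activity over hundreds
    of milliseconds.
    """
    state.validate()
    if kinetics is None:
        kinetics = default_params()["synapses"]["GABA_B"]
    k1, k2 = kinetics["K1_per_ms"], kinetics["K2_per_ms"]
    k3, k4 = kinetics["K3_per_ms"], kinetics["K4_per_ms"]
    kd, hill = kinetics["Kd"], kinetics["hill"]
    t = 1.0 if presyn_active else 0.0
    r = state.bound + dt * (k1 * t * (1.0 - state.bound) - k2 * state.bound)
    s = state.effector + dt * (k3 * state.bound - k4 * state.effector)
    r = min(max(r, 0.0), 1.0)
    s = max(s, 0.0)
    sn = s ** hill
    g = g_max_uS * sn / (sn + kd)
    return SlowInhibitionState(r, s), g


def slow_inhibition_drive(presyn_active: np.ndarray, dt: float,
                          g_max_uS: float = 1.0,
                          kinetics: dict | None = None) -> np.ndarray:
    """GABA_B conductance trace for a boolean presynaptic-activity trace."""
    if kinetics is None:
        kinetics = default_params()["synapses"]["GABA_B"]
    state = SlowInhibitionState()
    out = np.empty(len(presyn_active))
    for k, flag in enumerate(np.asarray(presyn_active, dtype=bool)):
        state, out[k] = step_slow_inhibition(state, bool(flag), dt,
                                             g_max_uS, kinetics)
    return out
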