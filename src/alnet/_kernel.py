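"""Numba kernel integrating the full antennal-lobe network.

PNs and eLNs share one membrane model ("E cells"), LNs another. Gating
steady states and relaxation factors are tabulated on a voltage grid
(built from the same rate functions as the single-cell module) and linearly
interpolated; the voltage uses an exponential-Euler update. Synaptic gating
is per presynaptic neuron (all synapses of one class from one cell share
kinetics), so postsynaptic conductances are weight-matrix/vector products.

Spike recording: E-cell spikes are upward 0 mV crossings; LN events are
local voltage maxima above −20 mV separated by ≥ 5 ms.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

from .cells import _ka_gates, _ln_ca_gates, _pn_rates

V_MIN, V_MAX, DV = -130.0, 70.0, 0.05

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_OVERFLOW = 2


def build_tables(pn_par: np.ndarray, ln_par: np.ndarray, dt: float):
    """Tabulate gate steady states and per-step relaxation factors."""
    n = int(round((V_MAX - V_MIN) / DV)) + 1
    v_grid = V_MIN + DV * np.arange(n)
    e_inf = np.empty((5, n))
    e_fac = np.empty((5, n))
    l_inf = np.empty((3, n))
    l_fac = np.empty((3, n))
    vt_e = pn_par[5]
    vt_l = ln_par[9]
    for i, v in enumerate(v_grid):
        am, bm, ah, bh, an, bn = _pn_rates(v, vt_e)
        for j, (a, b) in enumerate(((am, bm), (ah, bh), (an, bn))):
            e_inf[j, i] = a / (a + b)
            e_fac[j, i] = math.exp(-dt * (a + b))
        a_inf, tau_a, b_inf, tau_b = _ka_gates(v)
        e_inf[3, i], e_fac[3, i] = a_inf, math.exp(-dt / tau_a)
        e_inf[4, i], e_fac[4, i] = b_inf, math.exp(-dt / tau_b)
        mc_inf, tau_mc, hc_inf, tau_hc = _ln_ca_gates(v)
        l_inf[0, i], l_fac[0, i] = mc_inf, math.exp(-dt / tau_mc)
        l_inf[1, i], l_fac[1, i] = hc_inf, math.exp(-dt / tau_hc)
        w_inf = 1.0 / (1.0 + math.exp(-(v - vt_l - 30.0) / 5.0))
        tau_w = 6.0 / math.cosh((v - vt_l - 30.0) / 30.0)
        l_inf[2, i], l_fac[2, i] = w_inf, math.exp(-dt / tau_w)
    q_fac = math.exp(-dt / 50.0)
    return e_inf, e_fac, l_inf, l_fac, q_fac


@njit(cache=True, fastmath=True)
def _lookup(tab_inf, tab_fac, row, v, x):
    """Advance gate x toward its tabulated steady state at voltage v."""
    u = (v - V_MIN) / DV
    if u < 0.0:
        u = 0.0
    n = tab_inf.shape[1]
    if u > n - 2:
        u = float(n - 2)
    i = int(u)
    f = u - i
    xi = tab_inf[row, i] * (1.0 - f) + tab_inf[row, i + 1] * f
    xf = tab_fac[row, i] * (1.0 - f) + tab_fac[row, i + 1] * f
    return xi + (x - xi) * xf


@njit(cache=True, fastmath=True)
def integrate(
    nt, dt, n_pn, n_eln, n_ln,
    pn_par, ln_par,
    e_inf, e_fac, l_inf, l_fac, q_fac,
    ach_sinf, ach_eon, ach_eoff, ach_E, ach_thr,
    ga_sinf, ga_eon, ga_eoff, ga_E, ga_thr,
    gb_k1, gb_k2, gb_k3, gb_k4, gb_kd, gb_E, gb_thr,
    w_pn_from_eln, w_eln_from_pn, w_ln_from_pn, w_ln_from_eln,
    w_pn_from_ln_a, w_ln_from_ln, w_eln_from_ln, w_pn_from_ln_b,
    i_e, i_ln,
    v_e, g_e, v_l, g_l, ca_l,
    s_ach, s_ga, r_gb, s_gb,
    spike_cell, spike_time, ln_cell, ln_time,
    diag,
):
    """Integrate ``nt`` steps. Returns (status, n_e_spikes, n_ln_events)."""
    n_e = n_pn + n_eln
    cm_e, gl_e, el_e = pn_par[0], pn_par[1], pn_par[2]
    gna, ena = pn_par[3], pn_par[4]
    gk_e, ek_e = pn_par[6], pn_par[7]
    gka, eka = pn_par[8], pn_par[9]
    cm_l, gl_l, el_l = ln_par[0], ln_par[1], ln_par[2]
    gca, eca = ln_par[3], ln_par[4]
    gkca, ekca = ln_par[5], ln_par[6]
    gk_l, ek_l = ln_par[7], ln_par[8]
    ca_tau, ca_rest, ca_influx = ln_par[10], ln_par[11], ln_par[12]

    cap_e = spike_cell.shape[0]
    cap_l = ln_cell.shape[0]
    ne_spk = 0
    nl_spk = 0
    refr = 5.0

    v_l_prev1 = v_l.copy()
    last_ln = np.full(n_ln, -1e9)
    gb_unit = np.empty(n_ln)

    for k in range(nt):
        ms = int(k * dt)
        # --- synaptic gating from previous-step voltages ------------------
        for j in range(n_e):
            if v_e[j] > ach_thr:
                s_ach[j] = ach_sinf + (s_ach[j] - ach_sinf) * ach_eon
            else:
                s_ach[j] = s_ach[j] * ach_eoff
        for j in range(n_ln):
            active = v_l[j] > ga_thr
            if active:
                s_ga[j] = ga_sinf + (s_ga[j] - ga_sinf) * ga_eon
                r_gb[j] = r_gb[j] + dt * (gb_k1 * (1.0 - r_gb[j])
                                          - gb_k2 * r_gb[j])
            else:
                s_ga[j] = s_ga[j] * ga_eoff
                r_gb[j] = r_gb[j] - dt * gb_k2 * r_gb[j]
            s_gb[j] = s_gb[j] + dt * (gb_k3 * r_gb[j] - gb_k4 * s_gb[j])
            s4 = s_gb[j] * s_gb[j]
            s4 = s4 * s4
            gb_unit[j] = s4 / (s4 + gb_kd)

        s_pn = s_ach[:n_pn]
        s_eln = s_ach[n_pn:]
        g_ach_pn = np.dot(w_pn_from_eln, s_eln)
        g_ach_eln = np.dot(w_eln_from_pn, s_pn)
        g_ach_ln = np.dot(w_ln_from_pn, s_pn) + np.dot(w_ln_from_eln, s_eln)
        g_ga_pn = np.dot(w_pn_from_ln_a, s_ga)
        g_ga_ln = np.dot(w_ln_from_ln, s_ga)
        g_ga_eln = np.dot(w_eln_from_ln, s_ga)
        g_gb_pn = np.dot(w_pn_from_ln_b, gb_unit)

        # --- E cells (PNs then eLNs) --------------------------------------
        for j in range(n_e):
            v = v_e[j]
            m = _lookup(e_inf, e_fac, 0, v, g_e[0, j])
            h = _lookup(e_inf, e_fac, 1, v, g_e[1, j])
            nn = _lookup(e_inf, e_fac, 2, v, g_e[2, j])
            a = _lookup(e_inf, e_fac, 3, v, g_e[3, j])
            b = _lookup(e_inf, e_fac, 4, v, g_e[4, j])
            g_e[0, j], g_e[1, j], g_e[2, j] = m, h, nn
            g_e[3, j], g_e[4, j] = a, b
            gna_ = gna * m * m * m * h
            gk_ = gk_e * nn * nn * nn * nn
            gka_ = gka * a * a * a * a * b
            g_syn_exc = g_ach_pn[j] if j < n_pn else g_ach_eln[j - n_pn]
            g_syn_inh = g_ga_pn[j] if j < n_pn else g_ga_eln[j - n_pn]
            g_syn_slow = g_gb_pn[j] if j < n_pn else 0.0
            g_tot = gl_e + gna_ + gk_ + gka_ + g_syn_exc + g_syn_inh + g_syn_slow
            num = (gl_e * el_e + gna_ * ena + gk_ * ek_e + gka_ * eka
                   + g_syn_exc * ach_E + g_syn_inh * ga_E + g_syn_slow * gb_E
                   + i_e[j, ms])
            v_new = num / g_tot + (v - num / g_tot) * math.exp(
                -dt * g_tot * 1e-3 / cm_e)
            if not math.isfinite(v_new):
                diag[0] = float(j)
                diag[1] = k * dt
                return STATUS_NONFINITE, ne_spk, nl_spk
            v_e[j] = v_new
            if v < 0.0 <= v_new:
                if ne_spk < cap_e:
                    spike_cell[ne_spk] = j
                    spike_time[ne_spk] = (k + 1) * dt
                    ne_spk += 1
                else:
                    return STATUS_OVERFLOW, ne_spk, nl_spk

        # --- LNs ----------------------------------------------------------
        for j in range(n_ln):
            v = v_l[j]
            mc = _lookup(l_inf, l_fac, 0, v, g_l[0, j])
            hc = _lookup(l_inf, l_fac, 1, v, g_l[1, j])
            w = _lookup(l_inf, l_fac, 2, v, g_l[3, j])
            ca = ca_l[j]
            q_inf = ca * ca / (ca * ca + 4.0)
            q = q_inf + (g_l[2, j] - q_inf) * q_fac
            g_l[0, j], g_l[1, j], g_l[2, j], g_l[3, j] = mc, hc, q, w
            g_ca_ = gca * mc * mc * hc
            i_ca = g_ca_ * (v - eca)
            ca = ca + dt * (-ca_influx * i_ca - (ca - ca_rest) / ca_tau)
            if ca < 0.0:
                ca = 0.0
            ca_l[j] = ca
            g_kca_ = gkca * q
            gk_ = gk_l * w * w
            g_tot = (gl_l + g_ca_ + g_kca_ + gk_
                     + g_ach_ln[j] + g_ga_ln[j])
            num = (gl_l * el_l + g_ca_ * eca + g_kca_ * ekca + gk_ * ek_l
                   + g_ach_ln[j] * ach_E + g_ga_ln[j] * ga_E + i_ln[j, ms])
            v_new = num / g_tot + (v - num / g_tot) * math.exp(
                -dt * g_tot * 1e-3 / cm_l)
            if not math.isfinite(v_new):
                diag[0] = float(n_e + j)
                diag[1] = k * dt
                return STATUS_NONFINITE, ne_spk, nl_spk
            # local-max event detection on the previous sample
            if k >= 2 and v >= v_l_prev1[j] and v > v_new and v > -20.0:
                t_ev = k * dt
                if t_ev - last_ln[j] >= refr:
                    last_ln[j] = t_ev
                    if nl_spk < cap_l:
                        ln_cell[nl_spk] = j
                        ln_time[nl_spk] = t_ev
                        nl_spk += 1
                    else:
                        return STATUS_OVERFLOW, ne_spk, nl_spk
            v_l_prev1[j] = v
            v_l[j] = v_new

    return STATUS_OK, ne_spk, nl_spk
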