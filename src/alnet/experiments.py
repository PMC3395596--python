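"""Reproducible study drivers: the scaled experiments behind the headline
analyses (recruitment sweep, decorrelation, reliability/separability
trade-off and classification).

These functions run the network at a reduced scale — 150 PNs / 50 LNs /
25 eLNs by default, with per-cell conductance totals unchanged (in-degree
normalization makes per-cell drive independent of population size) — so
that a full experiment fits in minutes on one CPU. The full-size network
is available by passing the default :class:`~alnet.network.NetworkConfig`
sizes explicitly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import (
    bin_currents, compute_psth, odor_cross_trial_correlations,
    onset_correlation_series, optimization_surface, trial_correlations,
    window_bins,
)
from .classify import pair_error
from .network import NetworkConfig
from .simulate import Network, TrialProtocol, run_trial, trial_seed_for
from .stimulus import NoiseSpec, OdorSpec, trial_current

__all__ = ["scaled_config", "recruitment_sweep", "decorrelation_experiment",
           "tradeoff_experiment"]


def scaled_config(master_seed: int = 1, n_pn: int = 150, n_ln: int = 50,
                  n_eln: int = 25, **kw) -> NetworkConfig:
    """Reduced-size network with the default per-cell conductance totals."""
    return NetworkConfig(n_pn=n_pn, n_ln=n_ln, n_eln=n_eln,
                         seed=master_seed, **kw)


def _trial_psths(net: Network, odor: OdorSpec, proto: TrialProtocol,
                 noise: NoiseSpec, master_seed: int, odor_idx: int,
                 n_trials: int):
    out = []
    for t in range(n_trials):
        seed = trial_seed_for(master_seed, odor_idx, t)
        out.append(compute_psth(run_trial(net, odor, proto, noise, seed).pn))
    return np.array(out)


def recruitment_sweep(master_seed: int = 1,
                      ge_values=(0.0, 0.0004, 0.001),
                      gs_values=(0.0, 0.0004),
                      n_odors: int = 5, n_trials: int = 3,
                      config: NetworkConfig | None = None) -> pd.DataFrame:
    """Active-PN fraction during the stimulus across a conductance grid.

    Odors are spread around the ring; each (grid cell, odor, trial) row
    reports the fraction of PNs that fired at least once during the
    stimulus window and the total PN spike count.
    """
    if config is None:
        config = scaled_config(master_seed)
    base = Network.build(config)
    proto = TrialProtocol(post_ms=500.0)
    noise = NoiseSpec()
    centers = np.linspace(0, 300, n_odors, endpoint=False)
    rows = []
    for ge in ge_values:
        for gs in gs_values:
            net = base.with_conductances(ge, gs)
            for o, c in enumerate(centers):
                odor = OdorSpec.from_units(float(c))
                for t in range(n_trials):
                    seed = trial_seed_for(master_seed, o, t)
                    ras = run_trial(net, odor, proto, noise, seed).pn
                    counts = ras.counts(proto.pre_ms,
                                        proto.pre_ms + proto.stimulus_ms)
                    rows.append({"g_exc": ge, "g_slow": gs, "odor": o,
                                 "trial": t,
                                 "active_fraction": float((counts > 0).mean()),
                                 "n_spikes": int(counts.sum())})
    return pd.DataFrame(rows)


def decorrelation_experiment(master_seed: int = 1, g_exc: float = 0.0004,
                             g_slow: float = 0.0002, n_trials: int = 5,
                             odor_centers=(75.0, 80.0),
                             config: NetworkConfig | None = None) -> dict:
    """Onset-correlation and similar-odor correlation time series at one
    (g_exc, g_slow) cell, for PN responses and for the raw inputs.

    Returns per-bin series (trial-averaged) aligned on the PSTH bins, plus
    the stimulus-window bin indices.
    """
    if config is None:
        config = scaled_config(master_seed)
    net = Network.build(config).with_conductances(g_exc, g_slow)
    proto = TrialProtocol()
    L = proto.trial_length
    noise = NoiseSpec()
    odors = [OdorSpec.from_units(c) for c in odor_centers]
    pn_onset, in_onset = [], []
    psths = []
    inputs = []
    for o, odor in enumerate(odors):
        ps, ins = [], []
        for t in range(n_trials):
            seed = trial_seed_for(master_seed, o, t)
            mat = compute_psth(run_trial(net, odor, proto, noise, seed).pn)
            ps.append(mat)
            pn_onset.append(onset_correlation_series(mat.astype(float), L))
            cur = trial_current(odor, proto.pulse(), noise, "PN", seed,
                                config.n_pn)
            binned = bin_currents(cur, L)
            ins.append(binned)
            in_onset.append(onset_correlation_series(binned, L))
        psths.append(np.array(ps))
        inputs.append(np.array(ins))
    pn_pair = odor_cross_trial_correlations(psths[0], psths[1], L)
    in_pair = odor_cross_trial_correlations(inputs[0], inputs[1], L)
    return {
        "pn_onset_series": np.mean(pn_onset, axis=0),
        "input_onset_series": np.mean(in_onset, axis=0),
        "pn_similar_series": pn_pair["series"],
        "input_similar_series": in_pair["series"],
        "C_pn_similar": pn_pair["C"],
        "C_input_similar": in_pair["C"],
        "stimulus_bins": window_bins(L, proto.pre_ms,
                                     proto.pre_ms + proto.stimulus_ms),
        "trial_length_ms": L,
    }


def tradeoff_experiment(master_seed: int = 1,
                        ge_values=(0.0, 0.0004, 0.001),
                        gs_values=(0.0, 0.0002, 0.0004),
                        n_trials: int = 10, odor_centers=(75.0, 80.0),
                        config: NetworkConfig | None = None) -> dict:
    """Reliability/separability surfaces and classification error for a
    similar-odor pair over a (g_exc, g_slow) grid.

    Computes C_trials (within-odor), C_odors (across the similar pair,
    single-trial estimator), M = C_trials + (1 − C_odors) with its argmax,
    and the two-cluster classification error per grid cell.
    """
    if config is None:
        config = scaled_config(master_seed)
    base = Network.build(config)
    proto = TrialProtocol(post_ms=500.0)
    L = proto.trial_length
    noise = NoiseSpec()
    odors = [OdorSpec.from_units(c) for c in odor_centers]
    shape = (len(ge_values), len(gs_values))
    c_tr = np.zeros(shape)
    c_od = np.zeros(shape)
    err = np.zeros(shape)
    for i, ge in enumerate(ge_values):
        for j, gs in enumerate(gs_values):
            net = base.with_conductances(ge, gs)
            stacks = [_trial_psths(net, odor, proto, noise, master_seed, o,
                                   n_trials)
                      for o, odor in enumerate(odors)]
            c_tr[i, j] = np.mean([trial_correlations(s, L)["C_trials"]
                                  for s in stacks])
            c_od[i, j] = odor_cross_trial_correlations(stacks[0], stacks[1],
                                                       L)["C"]
            labels = [0] * n_trials + [1] * n_trials
            err[i, j] = pair_error(np.concatenate(stacks), labels, L)
    surface = optimization_surface(c_tr, c_od)
    return {"C_trials": c_tr, "C_odors": c_od, "M": surface["M"],
            "argmax": surface["argmax"], "error": err,
            "ge_values": tuple(ge_values), "gs_values": tuple(gs_values)}
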