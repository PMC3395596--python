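"""Trial and sweep simulation of the antennal-lobe network.

A trial is 3000 ms: 500 ms pre-stimulus, 1000 ms odor pulse, 1500 ms
post-stimulus, integrated at dt = 0.04 ms. A sweep enumerates a grid of
(g_exc, g_slow) conductance totals — the default 6 × 6 grid spans 0 to
0.001 µS in 0.0002 µS steps, giving the 36 excitation/inhibition ratios of
the study — and runs every odor of a panel for several trials per odor,
persisting PN spike rasters to an HDF5 archive with a manifest that records
every seed.

Noise seeds are derived per (odor, trial) only, so the same noise
realizations are used in every grid cell and comparisons across the grid
are paired.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import h5py
import numpy as np

from . import _kernel
from .cells import MembraneParams, steady_gates
from .network import Connectivity, NetworkConfig, build_connectivity, weight_matrix
from .params import default_params
from .raster import SpikeRaster
from .stimulus import NoiseSpec, OdorPanel, OdorSpec, PulseParams, trial_current

__all__ = [
    "TrialProtocol", "SweepGrid", "Network", "TrialResult",
    "run_trial", "run_experiment", "ei_ratio", "SimulationError",
    "load_raster", "archive_manifest",
]


class SimulationError(RuntimeError):
    """Numerical failure during integration, with trial diagnostics."""


@dataclass(frozen=True)
class TrialProtocol:
    """Timing of one odor trial and integration settings."""
    pre_ms: float = 500.0
    stimulus_ms: float = 1000.0
    post_ms: float = 1500.0
    dt: float = 0.04
    record: tuple[str, ...] = ("PN",)    # PN always; eLN/LN optional

    def __post_init__(self) -> None:
        if not (0 < self.dt <= 0.1):
            raise ValueError("dt must lie in (0, 0.1] ms")
        if "PN" not in self.record:
            raise ValueError("PN spikes are always recorded")

    @property
    def trial_length(self) -> float:
        return self.pre_ms + self.stimulus_ms + self.post_ms

    def pulse(self, rise_tau: float = 100.0, decay_tau: float = 200.0
              ) -> PulseParams:
        return PulseParams(onset=self.pre_ms, rise_tau=rise_tau,
                           decay_start=self.pre_ms + self.stimulus_ms,
                           decay_tau=decay_tau,
                           trial_length=self.trial_length)


@dataclass(frozen=True)
class SweepGrid:
    """Lists of g_exc and g_slow values (µS) enumerated by a sweep."""
    g_exc_values: tuple[float, ...] = (0.0, 0.0002, 0.0004, 0.0006, 0.0008, 0.001)
    g_slow_values: tuple[float, ...] = (0.0, 0.0002, 0.0004, 0.0006, 0.0008, 0.001)

    def __post_init__(self) -> None:
        for vals in (self.g_exc_values, self.g_slow_values):
            arr = np.asarray(vals)
            if np.any(arr < 0):
                raise ValueError("conductances must be >= 0")
            if np.any(np.diff(arr) <= 0):
                raise ValueError("grid values must be strictly increasing")

    def cells(self) -> list[tuple[float, float]]:
        return [(ge, gs) for ge in self.g_exc_values
                for gs in self.g_slow_values]

    def __len__(self) -> int:
        return len(self.g_exc_values) * len(self.g_slow_values)


def ei_ratio(g_exc: float, g_slow: float) -> float:
    """Excitation-to-inhibition ratio; defined as 5 when g_slow is zero."""
    if g_exc < 0 or g_slow < 0:
        raise ValueError("conductances must be >= 0")
    if g_slow == 0:
        return 5.0
    return g_exc / g_slow


@dataclass
class Network:
    """A built network: connectivity, weight matrices and cell parameters."""
    config: NetworkConfig
    conn: Connectivity
    weights: dict[str, np.ndarray]
    pn_params: MembraneParams
    ln_params: MembraneParams
    syn_params: dict

    @classmethod
    def build(cls, config: NetworkConfig, params: dict | None = None,
              conn: Connectivity | None = None) -> "Network":
        if params is None:
            params = default_params()
        if conn is None:
            conn = build_connectivity(config)
        weights = {
            "pn_from_eln": weight_matrix(conn, "eLN->PN", config.g_exc),
            "eln_from_pn": weight_matrix(conn, "PN->eLN", config.g_ach),
            "ln_from_pn": weight_matrix(conn, "PN->LN", config.g_ach),
            "ln_from_eln": weight_matrix(conn, "eLN->LN", config.g_exc),
            "pn_from_ln_a": weight_matrix(conn, "LN->PN", config.g_fast),
            "ln_from_ln": weight_matrix(conn, "LN->LN", config.g_fast),
            "eln_from_ln": weight_matrix(conn, "LN->eLN", config.g_fast),
            "pn_from_ln_b": weight_matrix(conn, "LN->PN", config.g_slow),
        }
        return cls(config=config, conn=conn, weights=weights,
                   pn_params=MembraneParams.from_dict("PN", params["cells"]["PN"]),
                   ln_params=MembraneParams.from_dict("LN", params["cells"]["LN"]),
                   syn_params=params["synapses"])

    def with_conductances(self, g_exc: float, g_slow: float) -> "Network":
        """Same connectivity and kinetics, new sweep conductances."""
        cfg = NetworkConfig(
            n_pn=self.config.n_pn, n_ln=self.config.n_ln,
            n_eln=self.config.n_eln, probabilities=self.config.probabilities,
            g_exc=g_exc, g_slow=g_slow, g_fast=self.config.g_fast,
            g_ach=self.config.g_ach, seed=self.config.seed)
        conn = Connectivity(adj=self.conn.adj, config=cfg)
        net = Network(config=cfg, conn=conn, weights={
            "pn_from_eln": weight_matrix(conn, "eLN->PN", g_exc),
            "eln_from_pn": self.weights["eln_from_pn"],
            "ln_from_pn": self.weights["ln_from_pn"],
            "ln_from_eln": weight_matrix(conn, "eLN->LN", g_exc),
            "pn_from_ln_a": self.weights["pn_from_ln_a"],
            "ln_from_ln": self.weights["ln_from_ln"],
            "eln_from_ln": self.weights["eln_from_ln"],
            "pn_from_ln_b": weight_matrix(conn, "LN->PN", g_slow),
        }, pn_params=self.pn_params, ln_params=self.ln_params,
            syn_params=self.syn_params)
        return net


@dataclass
class TrialResult:
    """Spike rasters per recorded cell class for one trial."""
    rasters: dict[str, SpikeRaster]

    @property
    def pn(self) -> SpikeRaster:
        return self.rasters["PN"]


def make_inputs(odor: OdorSpec, pulse: PulseParams, noise: NoiseSpec,
                config: NetworkConfig, trial_seed: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Input currents at 1 ms resolution: (E cells = PN then eLN, LNs)."""
    i_pn = trial_current(odor, pulse, noise, "PN", trial_seed, config.n_pn)
    i_eln = trial_current(odor, pulse, noise, "eLN", trial_seed, config.n_eln)
    i_ln = trial_current(odor, pulse, noise, "LN", trial_seed, config.n_ln)
    return np.vstack([i_pn, i_eln]), i_ln


def run_trial(network: Network, odor: OdorSpec, protocol: TrialProtocol,
              noise: NoiseSpec | None = None, trial_seed: int = 0,
              meta: dict | None = None) -> TrialResult:
    """Integrate one odor trial; deterministic given (network, seeds)."""
    cfg = network.config
    if noise is None:
        noise = NoiseSpec()
    pulse = protocol.pulse()
    i_e, i_ln = make_inputs(odor, pulse, noise, cfg, trial_seed)

    dt = protocol.dt
    nt = int(round(protocol.trial_length / dt))
    pn_par = network.pn_params.as_array()
    ln_par = network.ln_params.as_array()
    tabs = _kernel.build_tables(pn_par, ln_par, dt)

    syn = network.syn_params
    ach, ga, gb = syn["nACh"], syn["GABA_A"], syn["GABA_B"]

    def _first_order(rec):
        a, b = rec["alpha_per_ms"], rec["beta_per_ms"]
        return (a / (a + b), np.exp(-dt * (a + b)), np.exp(-dt * b),
                rec["E_mV"], rec["release_threshold_mV"])

    ach_c = _first_order(ach)
    ga_c = _first_order(ga)

    n_e = cfg.n_pn + cfg.n_eln
    v_e = np.full(n_e, network.pn_params.E_leak_mV)
    g_e = np.tile(steady_gates(network.pn_params,
                               network.pn_params.E_leak_mV)[:, None], (1, n_e))
    v_l = np.full(cfg.n_ln, network.ln_params.E_leak_mV)
    g_l = np.tile(steady_gates(network.ln_params,
                               network.ln_params.E_leak_mV)[:, None],
                  (1, cfg.n_ln))
    ca_l = np.full(cfg.n_ln, network.ln_params.ca_rest)
    s_ach = np.zeros(n_e)
    s_ga = np.zeros(cfg.n_ln)
    r_gb = np.zeros(cfg.n_ln)
    s_gb = np.zeros(cfg.n_ln)

    cap_e = int(n_e * protocol.trial_length / 1000.0 * 500) + 1000
    cap_l = int(cfg.n_ln * protocol.trial_length / 1000.0 * 300) + 1000
    spike_cell = np.empty(cap_e, dtype=np.int64)
    spike_time = np.empty(cap_e)
    ln_cell = np.empty(cap_l, dtype=np.int64)
    ln_time = np.empty(cap_l)
    diag = np.zeros(2)

    status, ne_spk, nl_spk = _kernel.integrate(
        nt, dt, cfg.n_pn, cfg.n_eln, cfg.n_ln,
        pn_par, ln_par, *tabs,
        *ach_c, *ga_c,
        gb["K1_per_ms"], gb["K2_per_ms"], gb["K3_per_ms"], gb["K4_per_ms"],
        gb["Kd"], gb["E_mV"], gb["release_threshold_mV"],
        network.weights["pn_from_eln"], network.weights["eln_from_pn"],
        network.weights["ln_from_pn"], network.weights["ln_from_eln"],
        network.weights["pn_from_ln_a"], network.weights["ln_from_ln"],
        network.weights["eln_from_ln"], network.weights["pn_from_ln_b"],
        i_e, i_ln,
        v_e, g_e, v_l, g_l, ca_l,
        s_ach, s_ga, r_gb, s_gb,
        spike_cell, spike_time, ln_cell, ln_time, diag,
    )
    if status == _kernel.STATUS_NONFINITE:
        raise SimulationError(
            f"non-finite voltage in cell {int(diag[0])} at t={diag[1]:.2f} ms "
            f"(odor meta={meta})")
    if status == _kernel.STATUS_OVERFLOW:
        raise SimulationError("spike buffer overflow — runaway network activity")

    meta = dict(meta or {})
    meta["trial_seed"] = int(trial_seed)
    cells = spike_cell[:ne_spk]
    times = spike_time[:ne_spk]
    rasters = {}
    pn_sel = cells < cfg.n_pn
    rasters["PN"] = SpikeRaster(cfg.n_pn, protocol.trial_length,
                                cells[pn_sel], times[pn_sel], dict(meta))
    if "eLN" in protocol.record:
        sel = ~pn_sel
        rasters["eLN"] = SpikeRaster(cfg.n_eln, protocol.trial_length,
                                     cells[sel] - cfg.n_pn, times[sel],
                                     dict(meta))
    if "LN" in protocol.record:
        rasters["LN"] = SpikeRaster(cfg.n_ln, protocol.trial_length,
                                    ln_cell[:nl_spk], ln_time[:nl_spk],
                                    dict(meta))
    return TrialResult(rasters=rasters)


# --------------------------------------------------------------------------
# sweep archive
# --------------------------------------------------------------------------

def trial_seed_for(master_seed: int, odor_idx: int, trial_idx: int) -> int:
    """Per-(odor, trial) child seed; identical across grid cells."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(odor_idx), int(trial_idx)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _manifest_dict(config: NetworkConfig, panel: OdorPanel, grid: SweepGrid,
                   n_trials: int, protocol: TrialProtocol, master_seed: int,
                   noise: NoiseSpec) -> dict:
    return {
        "config": {
            "n_pn": config.n_pn, "n_ln": config.n_ln, "n_eln": config.n_eln,
            "probabilities": config.probabilities,
            "g_fast": config.g_fast, "g_ach": config.g_ach,
            "seed": config.seed,
        },
        "panel": {"centers_units": list(panel.centers_units),
                  "sigma": panel.odors[0].sigma,
                  "peak_current_nA": panel.odors[0].peak_nA},
        "grid": {"g_exc": list(grid.g_exc_values),
                 "g_slow": list(grid.g_slow_values)},
        "n_trials": n_trials,
        "protocol": {"pre_ms": protocol.pre_ms,
                     "stimulus_ms": protocol.stimulus_ms,
                     "post_ms": protocol.post_ms, "dt": protocol.dt,
                     "record": list(protocol.record)},
        "noise": {"fraction": noise.fraction,
                  "correlation_time_ms": noise.correlation_time_ms,
                  "seed": noise.seed},
        "master_seed": master_seed,
    }


def _manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()


def run_experiment(config: NetworkConfig, panel: OdorPanel, grid: SweepGrid,
                   n_trials: int, protocol: TrialProtocol, path,
                   master_seed: int = 0, noise: NoiseSpec | None = None,
                   resume: bool = False, verbose: bool = False) -> dict:
    """Run odors × trials × grid and persist rasters to an HDF5 archive.

    One raster per (g_exc, g_slow, odor, trial). The manifest (config,
    seeds, grid) is stored in the file; re-running with ``resume=True``
    skips completed grid cells after verifying the manifest hash, and an
    existing archive without ``resume`` is refused.
    """
    if noise is None:
        noise = NoiseSpec()
    manifest = _manifest_dict(config, panel, grid, n_trials, protocol,
                              master_seed, noise)
    digest = _manifest_hash(manifest)
    exists = os.path.exists(path)
    if exists and not resume:
        raise FileExistsError(
            f"archive {path} exists; pass resume=True to continue it")
    mode = "a" if exists else "w"
    base = Network.build(config)
    with h5py.File(path, mode) as h5:
        if exists:
            if h5.attrs.get("manifest_hash") != digest:
                raise ValueError("archive manifest does not match this run")
        else:
            h5.attrs["manifest_json"] = json.dumps(manifest, sort_keys=True)
            h5.attrs["manifest_hash"] = digest
        for ge, gs in grid.cells():
            cell_name = f"gexc_{ge:g}_gslow_{gs:g}"
            if cell_name in h5 and h5[cell_name].attrs.get("complete", False):
                continue
            if cell_name in h5:
                del h5[cell_name]    # partial cell: recompute
            net = base.with_conductances(ge, gs)
            grp = h5.create_group(cell_name)
            grp.attrs["g_exc"] = ge
            grp.attrs["g_slow"] = gs
            for o_idx, odor in enumerate(panel.odors):
                for t_idx in range(n_trials):
                    seed = trial_seed_for(master_seed, o_idx, t_idx)
                    res = run_trial(net, odor, protocol, noise, seed,
                                    meta={"odor": o_idx, "trial": t_idx})
                    for cls, ras in res.rasters.items():
                        g = grp.create_group(f"{cls}/odor_{o_idx}/trial_{t_idx}")
                        g.create_dataset("neuron_ids", data=ras.neuron_ids)
                        g.create_dataset("times_ms", data=ras.times_ms)
                        g.attrs["trial_seed"] = seed
            grp.attrs["complete"] = True
            if verbose:
                print(f"completed {cell_name}")
    return manifest


def archive_manifest(path) -> dict:
    with h5py.File(path, "r") as h5:
        return json.loads(h5.attrs["manifest_json"])


def load_raster(path, g_exc: float, g_slow: float, odor_idx: int,
                trial_idx: int, cls: str = "PN") -> SpikeRaster:
    """Load one raster from a sweep archive."""
    with h5py.File(path, "r") as h5:
        manifest = json.loads(h5.attrs["manifest_json"])
        cell_name = f"gexc_{g_exc:g}_gslow_{g_slow:g}"
        g = h5[f"{cell_name}/{cls}/odor_{odor_idx}/trial_{trial_idx}"]
        n = {"PN": manifest["config"]["n_pn"],
             "LN": manifest["config"]["n_ln"],
             "eLN": manifest["config"]["n_eln"]}[cls]
        length = (manifest["protocol"]["pre_ms"]
                  + manifest["protocol"]["stimulus_ms"]
                  + manifest["protocol"]["post_ms"])
        return SpikeRaster(n, length, g["neuron_ids"][...], g["times_ms"][...],
                           {"odor": odor_idx, "trial": trial_idx,
                            "trial_seed": int(g.attrs["trial_seed"])})
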