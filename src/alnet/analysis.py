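"""Population-level analysis of PN spike rasters.

All correlation measures work on peri-stimulus time histograms: spike
counts in 50 ms bins overlapping by 25 ms, so a 3000 ms trial of 300 PNs
becomes a 300 × 120 matrix. The correlation between two population vectors
is the uncentered cosine of the angle between them (1 when both are zero,
0 when exactly one is zero), which is insensitive to uniform rate scaling;
the Euclidean distance complements it by tracking response amplitude.

The reliability/separability criterion is M = C_trials + (1 − C_odors):
C_trials is the time-averaged correlation across repeated trials of one
odor, C_odors across similar-odor pairs; both averages run over the bins
that intersect the stimulus window.
"""
from __future__ import annotations

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "BIN_MS", "HOP_MS", "compute_psth", "bin_windows", "window_bins",
    "onset_bin", "bin_currents", "cosine_correlation",
    "onset_correlation_series", "pairwise_correlation_series",
    "odor_pair_correlations", "trial_correlations",
    "odor_cross_trial_correlations",
    "euclidean_distance_series", "complexity_per_pn", "complexity_values",
    "optimization_surface", "response_histogram", "trajectory_summary",
]

BIN_MS = 50.0
HOP_MS = 25.0


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

def n_bins(trial_length_ms: float, hop_ms: float = HOP_MS) -> int:
    return int(np.ceil(trial_length_ms / hop_ms))

def bin_windows(trial_length_ms: float, bin_ms: float = BIN_MS,
                hop_ms: float = HOP_MS) -> np.ndarray:
    """(start, end) of every bin; the last bins truncate at trial end."""
    starts = hop_ms * np.arange(n_bins(trial_length_ms, hop_ms))
    ends = np.minimum(starts + bin_ms, trial_length_ms)
    return np.column_stack([starts, ends])


def compute_psth(raster: SpikeRaster, bin_ms: float = BIN_MS,
                 hop_ms: float = HOP_MS) -> np.ndarray:
    """Spike counts per (neuron, bin); each spike falls in ≤ 2 bins.

    Bins start at multiples of ``hop_ms`` from t = 0; a 3000 ms raster
    yields 120 columns. Spike times must lie inside the trial.
    """
    nb = n_bins(raster.trial_length_ms, hop_ms)
    out = np.zeros((raster.n_neurons, nb), dtype=np.int64)
    t = raster.times_ms
    if np.any((t < 0) | (t > raster.trial_length_ms)):
        raise ValueError("spike time outside trial bounds")
    k1 = np.minimum((t / hop_ms).astype(np.int64), nb - 1)
    np.add.at(out, (raster.neuron_ids, k1), 1)
    k0 = k1 - 1
    sel = (k0 >= 0) & (t < k0 * hop_ms + bin_ms)
    np.add.at(out, (raster.neuron_ids[sel], k0[sel]), 1)
    return out


def window_bins(trial_length_ms: float, t0: float, t1: float,
                bin_ms: float = BIN_MS, hop_ms: float = HOP_MS) -> np.ndarray:
    """Indices of bins whose windows intersect the open interval (t0, t1)."""
    w = bin_windows(trial_length_ms, bin_ms, hop_ms)
    return np.flatnonzero((w[:, 0] < t1) & (w[:, 1] > t0))


def onset_bin(trial_length_ms: float, onset_ms: float = 500.0,
              bin_ms: float = BIN_MS, hop_ms: float = HOP_MS) -> int:
    """First bin whose window intersects [onset, onset + bin]."""
    return int(window_bins(trial_length_ms, onset_ms, onset_ms + bin_ms,
                           bin_ms, hop_ms)[0])


def bin_currents(currents: np.ndarray, trial_length_ms: float,
                 dt_ms: float = 1.0, bin_ms: float = BIN_MS,
                 hop_ms: float = HOP_MS) -> np.ndarray:
    """Bin input currents with the PSTH's windows (mean per window)."""
    w = bin_windows(trial_length_ms, bin_ms, hop_ms)
    out = np.empty((currents.shape[0], len(w)))
    for k, (a, b) in enumerate(w):
        i0, i1 = int(a / dt_ms), max(int(a / dt_ms) + 1, int(b / dt_ms))
        out[:, k] = currents[:, i0:i1].mean(axis=1)
    return out


# --------------------------------------------------------------------------
# correlation and distance
# --------------------------------------------------------------------------

def cosine_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Uncentered cosine similarity with zero-vector conventions.

    Returns 1 if both vectors are zero (identical silence) and 0 if
    exactly one is zero.
    """
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 and nv == 0:
        return 1.0
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _per_bin_correlations(stack: np.ndarray) -> np.ndarray:
    """(n_resp, n_neurons, n_bins) → (n_bins, n_resp, n_resp) cosine matrices."""
    n_resp, _, nb = stack.shape
    out = np.empty((nb, n_resp, n_resp))
    for k in range(nb):
        x = stack[:, :, k]
        norms = np.linalg.norm(x, axis=1)
        dots = x @ x.T
        with np.errstate(invalid="ignore", divide="ignore"):
            c = dots / np.outer(norms, norms)
        zero = norms == 0
        c[zero, :] = 0.0
        c[:, zero] = 0.0
        both = np.outer(zero, zero)
        c[both] = 1.0
        np.fill_diagonal(c, 1.0)
        out[k] = c
    return out


def onset_correlation_series(mat: np.ndarray, trial_length_ms: float,
                             onset_ms: float = 500.0) -> np.ndarray:
    """Correlation between the onset-bin population vector and every
    subsequent bin.

    ``mat`` is a (n_neurons, n_bins) PSTH or identically binned input.
    """
    k0 = onset_bin(trial_length_ms, onset_ms)
    ref = mat[:, k0]
    return np.array([cosine_correlation(ref, mat[:, k])
                     for k in range(k0, mat.shape[1])])


def pairwise_correlation_series(stack: np.ndarray,
                                pairs: list[tuple[int, int]]) -> np.ndarray:
    """Mean correlation over the given response pairs, per bin."""
    mats = _per_bin_correlations(stack)
    idx = np.array(pairs)
    return mats[:, idx[:, 0], idx[:, 1]].mean(axis=1)


def odor_pair_correlations(stack: np.ndarray, trial_length_ms: float,
                           similar_pairs: list[tuple[int, int]],
                           dissimilar_pairs: list[tuple[int, int]] | None = None,
                           stim_window: tuple[float, float] = (500.0, 1500.0)):
    """Per-bin odor-pair correlation matrices and pair-averaged summaries.

    ``stack`` holds one (possibly trial-averaged) PSTH per odor:
    (n_odors, n_neurons, n_bins). Returns a dict with the per-bin matrices,
    per-bin similar/dissimilar averages, and the time-averaged C_odors over
    the bins intersecting the stimulus window.
    """
    mats = _per_bin_correlations(stack)
    bins = window_bins(trial_length_ms, *stim_window)
    out = {"matrices": mats}
    idx = np.array(similar_pairs)
    series = mats[:, idx[:, 0], idx[:, 1]].mean(axis=1)
    out["similar_series"] = series
    out["C_odors"] = float(series[bins].mean())
    if dissimilar_pairs:
        idx = np.array(dissimilar_pairs)
        series = mats[:, idx[:, 0], idx[:, 1]].mean(axis=1)
        out["dissimilar_series"] = series
        out["C_dissimilar"] = float(series[bins].mean())
    return out


def odor_cross_trial_correlations(stack_a: np.ndarray, stack_b: np.ndarray,
                                  trial_length_ms: float,
                                  stim_window: tuple[float, float] = (500.0, 1500.0)):
    """Correlation between two odors from single-trial responses.

    Averages the per-bin cosine over all cross-odor trial pairs, matching
    the estimator used for trial-to-trial correlations, so C_odors and
    C_trials are directly comparable. Returns the per-bin series and its
    stimulus-window time average C.
    """
    stack = np.concatenate([stack_a, stack_b]).astype(float)
    n1 = len(stack_a)
    mats = _per_bin_correlations(stack)
    series = mats[:, :n1, n1:].mean(axis=(1, 2))
    bins = window_bins(trial_length_ms, *stim_window)
    return {"series": series, "C": float(series[bins].mean())}


def trial_correlations(stack: np.ndarray, trial_length_ms: float,
                       stim_window: tuple[float, float] = (500.0, 1500.0)):
    """Per-bin trial-pair correlation matrices and C_trials.

    ``stack`` holds one single-trial PSTH per trial of one odor:
    (n_trials, n_neurons, n_bins). C_trials averages the off-diagonal
    entries over the stimulus-window bins.
    """
    mats = _per_bin_correlations(stack)
    n_tr = stack.shape[0]
    iu = np.triu_indices(n_tr, k=1)
    series = mats[:, iu[0], iu[1]].mean(axis=1)
    bins = window_bins(trial_length_ms, *stim_window)
    return {"matrices": mats, "series": series,
            "C_trials": float(series[bins].mean())}


def euclidean_distance_series(psth_a: np.ndarray, psth_b: np.ndarray,
                              trial_length_ms: float,
                              stim_window: tuple[float, float] = (500.0, 1500.0)):
    """Per-bin Euclidean distance between two responses + stimulus mean."""
    if psth_a.shape != psth_b.shape:
        raise ValueError("shape mismatch")
    series = np.linalg.norm(psth_a.astype(float) - psth_b.astype(float),
                            axis=0)
    bins = window_bins(trial_length_ms, *stim_window)
    return {"series": series, "stimulus_mean": float(series[bins].mean())}


# --------------------------------------------------------------------------
# response complexity
# --------------------------------------------------------------------------

def complexity_per_pn(responses: np.ndarray,
                      variance_threshold: float = 0.8) -> int:
    """Number of principal components explaining ≥ 80 % of the variance.

    ``responses`` is one PN's (n_odors × n_time_bins) response array — its
    trajectory through odor space over the stimulus. Zero total variance
    (static response) is defined as complexity 0.
    """
    x = np.asarray(responses, dtype=np.float64)
    xc = x - x.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(xc, compute_uv=False)
    var = sv ** 2
    total = var.sum()
    if total <= 0:
        return 0
    frac = np.cumsum(var) / total
    return int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)


def complexity_values(odor_trial_psths: np.ndarray, trial_length_ms: float,
                      stim_window: tuple[float, float] = (500.0, 1500.0),
                      bin_ms: float = BIN_MS) -> np.ndarray:
    """Complexity of every (PN, trial) from non-overlapping stimulus bins.

    ``odor_trial_psths`` has shape (n_odors, n_trials, n_neurons, n_bins)
    built with *non-overlapping* ``bin_ms`` bins over the full trial, or a
    raster-derived count array; here we expect counts in non-overlapping
    50 ms bins covering the stimulus window (n_odors, n_trials, n_neurons,
    20). Returns n_neurons × n_trials integers flattened to one array.
    """
    n_odors, n_trials, n_neurons, nb = odor_trial_psths.shape
    out = np.empty(n_neurons * n_trials, dtype=np.int64)
    i = 0
    for tr in range(n_trials):
        for n in range(n_neurons):
            out[i] = complexity_per_pn(odor_trial_psths[:, tr, n, :])
            i += 1
    return out


def stimulus_window_counts(raster: SpikeRaster, bin_ms: float = BIN_MS,
                           stim_window: tuple[float, float] = (500.0, 1500.0)
                           ) -> np.ndarray:
    """Counts in non-overlapping 50 ms bins over the stimulus window."""
    t0, t1 = stim_window
    nb = int(round((t1 - t0) / bin_ms))
    out = np.zeros((raster.n_neurons, nb), dtype=np.int64)
    sel = (raster.times_ms >= t0) & (raster.times_ms < t1)
    k = ((raster.times_ms[sel] - t0) / bin_ms).astype(np.int64)
    np.add.at(out, (raster.neuron_ids[sel], k), 1)
    return out


# --------------------------------------------------------------------------
# optimization surface, response histogram, trajectories
# --------------------------------------------------------------------------

def optimization_surface(c_trials: np.ndarray, c_odors: np.ndarray):
    """M = C_trials + (1 − C_odors) per grid cell, with its argmax."""
    c_trials = np.asarray(c_trials, dtype=np.float64)
    c_odors = np.asarray(c_odors, dtype=np.float64)
    if c_trials.shape != c_odors.shape:
        raise ValueError("grid shape mismatch")
    m = c_trials + (1.0 - c_odors)
    arg = np.unravel_index(int(np.argmax(m)), m.shape)
    return {"M": m, "argmax": arg}


def response_histogram(rasters: list[SpikeRaster],
                       stim_window: tuple[float, float] = (500.0, 1500.0)):
    """Distribution of per-PN spike counts during the stimulus.

    Pools all given rasters; returns (counts, proportions) where
    ``proportions[k]`` is the fraction of (PN, trial) observations with k
    spikes. Proportions sum to 1.
    """
    counts = np.concatenate([r.counts(*stim_window) for r in rasters])
    hist = np.bincount(counts)
    return {"counts": np.arange(len(hist)), "proportion": hist / counts.size}


def trajectory_summary(mean_psth: np.ndarray, trial_length_ms: float,
                       onset_ms: float = 500.0, n_components: int = 3):
    """Project trial-averaged population activity onto its first PCs.

    Rows (neurons) are mean-centered across time; the baseline is the mean
    of the pre-stimulus bins in PC space; the amplitude series is the
    distance from baseline, also returned normalized by its maximum.
    """
    x = np.asarray(mean_psth, dtype=np.float64)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    pcs = (u[:, :n_components].T @ xc)          # (n_components, n_bins)
    pre = window_bins(trial_length_ms, 0.0, onset_ms)
    pre = pre[:-1] if len(pre) > 1 else pre     # drop bin straddling onset
    baseline = pcs[:, pre].mean(axis=1)
    amp = np.linalg.norm(pcs - baseline[:, None], axis=0)
    peak = amp.max()
    norm_amp = amp / peak if peak > 0 else amp
    t_max = float(np.argmax(amp) * HOP_MS)
    return {"pcs": pcs, "baseline": baseline, "amplitude": amp,
            "normalized_amplitude": norm_amp, "time_to_max_ms": t_max}
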