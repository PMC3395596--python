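"""Odor classification by hierarchical clustering of single-trial responses.

The distance between two single-trial responses i and j is d_ij = 1 − c_ij,
where c_ij is their correlation (cosine) averaged over the stimulus-window
bins. Responses of two odors (default 20 trials each) are clustered into
two groups by agglomerative linkage (single by default); each cluster is
assigned to an odor both ways and the error count is
N_err = min(N_err1, N_err2), so the error proportion N_err / N_total never
exceeds 0.5 (chance level).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .analysis import window_bins, _per_bin_correlations

__all__ = ["ResponseDistanceMatrix", "ClassificationOutcome",
           "response_distance", "cluster_two", "classification_error",
           "error_surface", "pair_error"]


@dataclass
class ResponseDistanceMatrix:
    """Pairwise correlation distances between single-trial responses."""
    d: np.ndarray                   # (n, n), symmetric, zero diagonal
    labels: np.ndarray              # true odor per response
    degenerate: np.ndarray          # responses with no spikes at all

    def __post_init__(self) -> None:
        d = self.d
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if d.min() < -1e-9 or d.max() > 2 + 1e-9:
            raise ValueError("entries must lie in [0, 2]")


@dataclass
class ClassificationOutcome:
    """Two-cluster assignment and its error under the best odor mapping."""
    assignment: np.ndarray
    n_err1: int
    n_err2: int

    @property
    def n_err(self) -> int:
        return min(self.n_err1, self.n_err2)

    @property
    def error_proportion(self) -> float:
        return self.n_err / len(self.assignment)


def response_distance(stack: np.ndarray, labels, trial_length_ms: float,
                      stim_window: tuple[float, float] = (500.0, 1500.0)
                      ) -> ResponseDistanceMatrix:
    """Build d_ij = 1 − c_ij from single-trial PSTHs.

    ``stack`` is (n_responses, n_neurons, n_bins); ``labels`` gives the
    true odor of each response. c_ij is the per-bin cosine correlation
    averaged over the bins intersecting the stimulus window.
    """
    stack = np.asarray(stack)
    bins = window_bins(trial_length_ms, *stim_window)
    mats = _per_bin_correlations(stack[:, :, bins])
    c = mats.mean(axis=0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    degenerate = stack[:, :, bins].sum(axis=(1, 2)) == 0
    return ResponseDistanceMatrix(d=d, labels=np.asarray(labels),
                                  degenerate=degenerate)


def cluster_two(dist: ResponseDistanceMatrix | np.ndarray,
                method: str = "single") -> np.ndarray:
    """Cut the agglomerative merge tree at exactly two clusters.

    Deterministic: scipy's linkage breaks ties by index order. Returns a
    0/1 assignment per response.
    """
    d = dist.d if isinstance(dist, ResponseDistanceMatrix) else np.asarray(dist)
    if d.shape[0] < 2:
        raise ValueError("need at least two responses")
    z = linkage(squareform(d, checks=False), method=method)
    labels = fcluster(z, t=2, criterion="maxclust")
    return (labels == labels[0]).astype(int)


def classification_error(assignment: np.ndarray, true_labels: np.ndarray
                         ) -> ClassificationOutcome:
    """Errors under both cluster-to-odor mappings; keep the minimum."""
    assignment = np.asarray(assignment)
    true_labels = np.asarray(true_labels)
    if assignment.shape != true_labels.shape:
        raise ValueError("assignment and labels must align")
    odors = np.unique(true_labels)
    if len(odors) != 2:
        raise ValueError("exactly two true odors required")
    truth = (true_labels == odors[0]).astype(int)
    n_err1 = int(np.sum(assignment != truth))
    n_err2 = int(np.sum(assignment != (1 - truth)))
    return ClassificationOutcome(assignment=assignment,
                                 n_err1=n_err1, n_err2=n_err2)


def pair_error(stack: np.ndarray, labels, trial_length_ms: float,
               method: str = "single",
               stim_window: tuple[float, float] = (500.0, 1500.0)) -> float:
    """Error proportion for one odor pair from single-trial PSTHs."""
    dist = response_distance(stack, labels, trial_length_ms, stim_window)
    assignment = cluster_two(dist, method=method)
    return classification_error(assignment, dist.labels).error_proportion


def error_surface(psth_loader, grid_cells, odor_pairs, n_trials: int,
                  trial_length_ms: float, method: str = "single"):
    """Mean classification error per (g_exc, g_slow) grid cell.

    ``psth_loader(g_exc, g_slow, odor_idx, trial_idx)`` must return the
    single-trial PSTH matrix. Missing responses raise (they are never
    silently skipped). Returns a dict mapping grid cell → mean error over
    the odor pairs.
    """
    out = {}
    for ge, gs in grid_cells:
        errs = []
        for o1, o2 in odor_pairs:
            stack, labels = [], []
            for odor in (o1, o2):
                for tr in range(n_trials):
                    mat = psth_loader(ge, gs, odor, tr)
                    if mat is None:
                        raise KeyError(
                            f"missing raster: cell=({ge}, {gs}) odor={odor} "
                            f"trial={tr}")
                    stack.append(mat)
                    labels.append(odor)
            errs.append(pair_error(np.array(stack), labels,
                                   trial_length_ms, method))
        out[(ge, gs)] = float(np.mean(errs))
    return out
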