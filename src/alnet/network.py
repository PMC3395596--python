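"""Antennal-lobe network construction.

The default network has 300 PNs, 100 inhibitory LNs and 50 excitatory eLNs,
wired by independent Bernoulli draws per ordered cell pair with pathway-
specific probabilities (PN→LN 0.5, PN→eLN 0.5, eLN→PN 0.1, eLN→LN 0.5,
LN→PN 0.5, LN→LN 0.5, LN→eLN 0.5). There are no self-connections within a
population and no eLN→eLN pathway.

Per-synapse maximal conductances are normalized by the target cell's
in-degree so that the summed maximum per target equals the configured
pathway total. This makes the sweep variables ``g_exc`` (total eLN-mediated
lateral excitation per cell) and ``g_slow`` (total GABA_B inhibition per
PN) invariant to population size and connection probability.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NetworkConfig", "Connectivity", "build_connectivity",
           "assign_conductances", "PATHWAYS", "DEFAULT_PROBABILITIES"]

# (pathway name, presynaptic population, postsynaptic population)
PATHWAYS = (
    ("PN->LN", "PN", "LN"),
    ("PN->eLN", "PN", "eLN"),
    ("eLN->PN", "eLN", "PN"),
    ("eLN->LN", "eLN", "LN"),
    ("LN->PN", "LN", "PN"),
    ("LN->LN", "LN", "LN"),
    ("LN->eLN", "LN", "eLN"),
)

DEFAULT_PROBABILITIES = {
    "PN->LN": 0.5,
    "PN->eLN": 0.5,
    "eLN->PN": 0.1,
    "eLN->LN": 0.5,
    "LN->PN": 0.5,
    "LN->LN": 0.5,
    "LN->eLN": 0.5,
}


@dataclass(frozen=True)
class NetworkConfig:
    """Population sizes, connection probabilities and conductance budgets.

    ``g_exc`` and ``g_slow`` are the two sweep variables of the study:
    the total eLN-mediated excitatory conductance per target cell and the
    total GABA_B (slow inhibitory) conductance per PN, both in µS.
    ``g_fast`` (GABA_A) and ``g_ach`` (PN-sourced cholinergic drive) are the
    fixed lateral pathways.
    """
    n_pn: int = 300
    n_ln: int = 100
    n_eln: int = 50
    probabilities: dict = field(default_factory=lambda: dict(DEFAULT_PROBABILITIES))
    g_exc: float = 0.0004
    g_slow: float = 0.0002
    g_fast: float = 0.002
    g_ach: float = 0.0075
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pn, self.n_ln, self.n_eln) <= 0:
            raise ValueError("population counts must be > 0")
        for name, _, _ in PATHWAYS:
            p = self.probabilities.get(name, DEFAULT_PROBABILITIES[name])
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"connection probability {name} outside [0, 1]")
        for g in (self.g_exc, self.g_slow, self.g_fast, self.g_ach):
            if g < 0:
                raise ValueError("conductance totals must be >= 0")

    def size(self, population: str) -> int:
        return {"PN": self.n_pn, "LN": self.n_ln, "eLN": self.n_eln}[population]


@dataclass
class Connectivity:
    """Boolean adjacency per pathway: ``adj[name][pre, post]``."""
    adj: dict[str, np.ndarray]
    config: NetworkConfig

    def density(self, pathway: str) -> float:
        """Realized fraction of connected ordered pairs (self-pairs excluded
        for within-population pathways)."""
        a = self.adj[pathway]
        total = a.size
        if pathway == "LN->LN":
            total -= min(a.shape)
        return a.sum() / total

    def in_degree(self, pathway: str) -> np.ndarray:
        return self.adj[pathway].sum(axis=0)


def build_connectivity(config: NetworkConfig) -> Connectivity:
    """Draw the probabilistic adjacency for every pathway.

    Each ordered (pre, post) pair is connected independently with the
    pathway probability; reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    adj = {}
    for name, pre, post in PATHWAYS:
        p = config.probabilities.get(name, DEFAULT_PROBABILITIES[name])
        a = rng.random((config.size(pre), config.size(post))) < p
        if pre == post:
            np.fill_diagonal(a, False)   # no self-connections
        adj[name] = a
    return Connectivity(adj=adj, config=config)


def _pathway_total(name: str, config: NetworkConfig) -> float:
    """Total maximal conductance per target cell for a pathway."""
    if name.startswith("eLN->"):
        return config.g_exc
    if name.startswith("PN->"):
        return config.g_ach
    return config.g_fast       # LN->* fast GABA_A


def assign_conductances(conn: Connectivity,
                        config: NetworkConfig | None = None) -> pd.DataFrame:
    """Per-synapse maximal conductances as an edge table.

    For every target cell and pathway the per-synapse maximum equals the
    pathway's per-cell total divided by the target's in-degree, so the sum
    of maxima per cell equals the configured total exactly (cells with
    in-degree 0 receive nothing). The slow GABA_B pathway shares the LN→PN
    adjacency and distributes ``g_slow`` the same way.

    Returns a DataFrame with columns (pathway, pre_index, post_index,
    g_max_uS), 0-based indices.
    """
    if config is None:
        config = conn.config
    rows = []
    for name, _, _ in PATHWAYS:
        a = conn.adj[name]
        indeg = a.sum(axis=0)
        total = _pathway_total(name, config)
        pre_idx, post_idx = np.nonzero(a)
        g = np.where(indeg[post_idx] > 0, total / indeg[post_idx], 0.0)
        rows.append(pd.DataFrame({"pathway": name, "pre_index": pre_idx,
                                  "post_index": post_idx, "g_max_uS": g}))
        if name == "LN->PN":
            g_b = np.where(indeg[post_idx] > 0,
                           config.g_slow / indeg[post_idx], 0.0)
            rows.append(pd.DataFrame({"pathway": "LN->PN:GABA_B",
                                      "pre_index": pre_idx,
                                      "post_index": post_idx,
                                      "g_max_uS": g_b}))
    return pd.concat(rows, ignore_index=True)


def weight_matrix(conn: Connectivity, pathway: str, total: float) -> np.ndarray:
    """Dense (post, pre) weight matrix with in-degree-normalized maxima."""
    a = conn.adj[pathway]
    indeg = a.sum(axis=0).astype(float)
    w = np.zeros(a.T.shape)
    nz = indeg > 0
    w[nz, :] = (a.T[nz, :] * (total / indeg[nz, None]))
    return w


def export_edge_list(conn: Connectivity, path) -> None:
    """Write the synapse table as edge-list CSV."""
    assign_conductances(conn).to_csv(path, index=False)


def import_edge_list(path) -> pd.DataFrame:
    """Read an edge-list CSV written by :func:`export_edge_list`."""
    df = pd.read_csv(path)
    expected = {"pathway", "pre_index", "post_index", "g_max_uS"}
    if set(df.columns) != expected:
        raise ValueError(f"edge list must have columns {sorted(expected)}")
    return df
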