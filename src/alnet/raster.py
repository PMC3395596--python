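"""Spike-raster container and plain-text / HDF5 persistence.

A :class:`SpikeRaster` holds spike times for one trial of one odor as
parallel arrays (neuron id, time in ms) plus metadata (odor, trial,
configuration hash, seeds). The CSV format has columns
``neuron_id, spike_time_ms, trial, odor``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """Spike times per neuron for a single trial."""
    n_neurons: int
    trial_length_ms: float
    neuron_ids: np.ndarray          # int array, one entry per spike
    times_ms: np.ndarray            # float array, same length
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        if self.neuron_ids.shape != self.times_ms.shape:
            raise ValueError("neuron_ids and times_ms must have equal length")
        if len(self.times_ms) and (self.times_ms.min() < 0
                                   or self.times_ms.max() > self.trial_length_ms):
            raise ValueError("spike times outside [0, trial_length]")
        if len(self.neuron_ids) and (self.neuron_ids.min() < 0
                                     or self.neuron_ids.max() >= self.n_neurons):
            raise ValueError("neuron id outside [0, n_neurons)")
        order = np.lexsort((self.times_ms, self.neuron_ids))
        self.neuron_ids = self.neuron_ids[order]
        self.times_ms = self.times_ms[order]

    @property
    def n_spikes(self) -> int:
        return len(self.times_ms)

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.times_ms[self.neuron_ids == neuron]

    def counts(self, t0: float, t1: float) -> np.ndarray:
        """Spike count per neuron in the half-open window [t0, t1)."""
        sel = (self.times_ms >= t0) & (self.times_ms < t1)
        return np.bincount(self.neuron_ids[sel], minlength=self.n_neurons)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": self.neuron_ids,
            "spike_time_ms": self.times_ms,
            "trial": self.meta.get("trial", 0),
            "odor": self.meta.get("odor", 0),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_neurons: int,
                       trial_length_ms: float, meta: dict | None = None
                       ) -> "SpikeRaster":
        return cls(n_neurons, trial_length_ms,
                   df["neuron_id"].to_numpy(), df["spike_time_ms"].to_numpy(),
                   dict(meta or {}))

    @classmethod
    def from_csv(cls, path, n_neurons: int, trial_length_ms: float
                 ) -> "SpikeRaster":
        df = pd.read_csv(path)
        meta = {}
        if len(df):
            meta = {"trial": int(df["trial"].iloc[0]),
                    "odor": int(df["odor"].iloc[0])}
        return cls.from_dataframe(df, n_neurons, trial_length_ms, meta)
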