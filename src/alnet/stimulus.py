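"""Synthetic odor input: Gaussian profiles on a neuron ring, pulse
envelopes, noise, the odor panel, and surrogate spike rasters.

An odor is a Gaussian intensity profile over a circular arrangement of
neurons. Neuron ``i`` of a population of ``n`` sits at ring coordinate
``x_i = -1 + 2 i / n``; the profile is ``exp(-d(x, c)^2 / (2 σ^2))`` with
``d`` the circular distance (period 2), truncated to zero below 0.1 of the
peak. Odor identity is the profile center ``c``; odor similarity is the
circular shift between centers, measured in *units* of one PN index step on
the default 300-PN ring (so 1 unit = 2/300 in x, and the maximum possible
shift is 150 units). Similar odors are shifted by 5 units, dissimilar by
40.

The temporal envelope is a current pulse: exponential rise (τ = 100 ms)
from stimulus onset (500 ms), exponential decay (τ = 200 ms) after decay
start (1500 ms). Each neuron's input current is
``peak_current × profile × envelope + noise`` where the noise is a
low-pass-filtered Gaussian process (~5–10 % of the stimulus amplitude),
independent across neurons and trials.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import default_params
from .raster import SpikeRaster

__all__ = [
    "RING_SIZE", "OdorSpec", "PulseParams", "NoiseSpec", "OdorPanel",
    "gaussian_profile", "circular_shift_distance", "pulse_envelope",
    "trial_current", "surrogate_raster", "ring_coordinates",
]

RING_SIZE = 300          # PN indices that define the odor "unit"
_CLASS_IDS = {"PN": 0, "eLN": 1, "LN": 2}


def ring_coordinates(n_neurons: int) -> np.ndarray:
    """Ring coordinate x ∈ [−1, 1) of each neuron in a population."""
    return -1.0 + 2.0 * np.arange(n_neurons) / n_neurons


def units_to_x(units: float, ring_size: int = RING_SIZE) -> float:
    """Convert a center given in PN-index units to the x coordinate."""
    return -1.0 + 2.0 * units / ring_size


@dataclass(frozen=True)
class OdorSpec:
    """One odor: center (x-coordinate), width, floor and peak current."""
    center: float                 # x ∈ [−1, 1), wraps circularly
    sigma: float = 0.15           # Gaussian width in x units
    truncation: float = 0.1      # profile floor as a fraction of the peak
    peak_current_nA: float | None = None   # None → parameter-file default

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0.0 <= self.truncation < 1.0):
            raise ValueError("truncation must lie in [0, 1)")

    @classmethod
    def from_units(cls, units: float, ring_size: int = RING_SIZE,
                   **kw) -> "OdorSpec":
        return cls(center=units_to_x(units, ring_size), **kw)

    @property
    def peak_nA(self) -> float:
        if self.peak_current_nA is not None:
            return self.peak_current_nA
        return default_params()["input"]["peak_current_nA"]


@dataclass(frozen=True)
class PulseParams:
    """Temporal envelope of an odor presentation (times in ms)."""
    onset: float = 500.0
    rise_tau: float = 100.0
    decay_start: float = 1500.0
    decay_tau: float = 200.0
    trial_length: float = 3000.0

    def __post_init__(self) -> None:
        if not (self.onset < self.decay_start < self.trial_length):
            raise ValueError("require onset < decay_start < trial_length")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Low-pass-filtered Gaussian input noise.

    ``fraction`` is the noise standard deviation relative to the stimulus
    peak amplitude; ``correlation_time_ms`` the filter time constant.
    """
    fraction: float = 0.10
    correlation_time_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.correlation_time_ms <= 0:
            raise ValueError("correlation time must be > 0")


def gaussian_profile(odor: OdorSpec, n_neurons: int) -> np.ndarray:
    """Per-neuron amplitude (dimensionless, peak 1, floor-truncated).

    The profile wraps around the ring and is symmetric about the center.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    x = ring_coordinates(n_neurons)
    d = np.abs(x - odor.center)
    d = np.minimum(d, 2.0 - d)          # circular distance, period 2
    g = np.exp(-0.5 * (d / odor.sigma) ** 2)
    g[g < odor.truncation] = 0.0
    return g


def circular_shift_distance(center_a: float, center_b: float,
                            ring_size: int = RING_SIZE) -> float:
    """Shift between two odor centers in units, on a ring of ``ring_size``.

    Centers are given in units (PN index steps). The maximum attainable
    value is ``ring_size / 2`` (150 on the default ring).
    """
    d = abs(center_a - center_b) % ring_size
    return min(d, ring_size - d)


def pulse_envelope(t, p: PulseParams):
    """Envelope value(s) in [0, 1] at time(s) ``t`` (ms).

    Zero before onset; saturating exponential rise; exponential decay after
    ``decay_start``; continuous everywhere.
    """
    t = np.asarray(t, dtype=np.float64)
    rise = 1.0 - np.exp(-(t - p.onset) / p.rise_tau)
    at_decay = 1.0 - np.exp(-(p.decay_start - p.onset) / p.rise_tau)
    decay = at_decay * np.exp(-(t - p.decay_start) / p.decay_tau)
    env = np.where(t < p.onset, 0.0, np.where(t < p.decay_start, rise, decay))
    return env if env.ndim else float(env)


@dataclass(frozen=True)
class OdorPanel:
    """A list of odors at successive circular shifts of one profile.

    The default panel has 21 odors at 5-unit steps (shifts 0…100 relative
    to the first odor). Similar pairs are those shifted by 5 units
    (adjacent panel odors); dissimilar pairs are shifted by 40 units.
    """
    odors: tuple[OdorSpec, ...]
    centers_units: tuple[float, ...]
    step_units: float = 5.0
    ring_size: int = RING_SIZE

    def __post_init__(self) -> None:
        mods = [round(c % self.ring_size, 9) for c in self.centers_units]
        if len(set(mods)) != len(mods):
            raise ValueError("odor centers must be distinct modulo ring size")

    def __len__(self) -> int:
        return len(self.odors)

    @classmethod
    def default(cls, n_odors: int = 21, step_units: float = 5.0,
                start_units: float = 0.0, ring_size: int = RING_SIZE,
                **odor_kw) -> "OdorPanel":
        centers = tuple(start_units + k * step_units for k in range(n_odors))
        odors = tuple(OdorSpec.from_units(c, ring_size, **odor_kw)
                      for c in centers)
        return cls(odors=odors, centers_units=centers,
                   step_units=step_units, ring_size=ring_size)

    def pairs_at_shift(self, shift_units: float) -> list[tuple[int, int]]:
        """All odor index pairs whose circular shift equals ``shift_units``."""
        out = []
        for i in range(len(self)):
            for j in range(i + 1, len(self)):
                d = circular_shift_distance(self.centers_units[i],
                                            self.centers_units[j],
                                            self.ring_size)
                if np.isclose(d, shift_units):
                    out.append((i, j))
        return out

    def similar_pairs(self) -> list[tuple[int, int]]:
        return self.pairs_at_shift(5.0)

    def dissimilar_pairs(self) -> list[tuple[int, int]]:
        return self.pairs_at_shift(40.0)


def _filtered_noise(rng: np.random.Generator, n_neurons: int, nt: int,
                    dt_ms: float, tau_ms: float) -> np.ndarray:
    """Unit-variance Ornstein–Uhlenbeck noise, stationary start."""
    rho = np.exp(-dt_ms / tau_ms)
    drive = np.sqrt(1.0 - rho * rho)
    out = np.empty((n_neurons, nt))
    state = rng.standard_normal(n_neurons)
    for k in range(nt):
        out[:, k] = state
        state = rho * state + drive * rng.standard_normal(n_neurons)
    return out


def class_input_scale(neuron_class: str) -> float:
    """Relative input amplitude for a cell class (PN-normalized)."""
    return default_params()["input"]["class_scale"][neuron_class]


def class_sigma_scale(neuron_class: str) -> float:
    """Relative input-profile width for a cell class.

    eLNs receive a narrower version of the PN profile (the eLN input width
    is scaled down by the eLN/PN population ratio), so similar odors drive
    distinctly different eLN subsets.
    """
    return default_params()["input"]["class_sigma_scale"][neuron_class]


def trial_current(odor: OdorSpec, pulse: PulseParams, noise: NoiseSpec,
                  neuron_class: str = "PN", trial_seed: int = 0,
                  n_neurons: int = RING_SIZE, dt_ms: float = 1.0
                  ) -> np.ndarray:
    """Per-neuron input current time series (nA) for one trial.

    ``current = peak × profile × envelope + noise`` with the profile
    sampled on the class's own ring (eLN/LN profiles are class-scaled
    versions of the PN profile) and noise reproducible from
    ``(trial_seed, neuron_class)``.
    """
    scale = class_input_scale(neuron_class)
    sig = class_sigma_scale(neuron_class)
    prof_odor = odor if sig == 1.0 else OdorSpec(
        center=odor.center, sigma=odor.sigma * sig,
        truncation=odor.truncation, peak_current_nA=odor.peak_current_nA)
    prof = gaussian_profile(prof_odor, n_neurons)
    nt = int(round(pulse.trial_length / dt_ms))
    t = np.arange(nt) * dt_ms
    env = pulse_envelope(t, pulse)
    peak = odor.peak_nA * scale
    cur = peak * prof[:, None] * env[None, :]
    if noise.fraction > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(trial_seed),
                                   spawn_key=(_CLASS_IDS[neuron_class],
                                              int(noise.seed))))
        cur = cur + (noise.fraction * peak) * _filtered_noise(
            rng, n_neurons, nt, dt_ms, noise.correlation_time_ms)
    return cur


def surrogate_raster(odor: OdorSpec, n_neurons: int, trial_seed: int,
                     pulse: PulseParams | None = None,
                     peak_rate_hz: float = 20.0, dt_ms: float = 1.0,
                     meta: dict | None = None) -> SpikeRaster:
    """Inhomogeneous-Poisson raster whose rate follows profile × envelope.

    A fast stand-in for network simulation, used to exercise the analysis
    and classification stages.
    """
    if pulse is None:
        pulse = PulseParams()
    rng = np.random.default_rng(int(trial_seed))
    prof = gaussian_profile(odor, n_neurons)
    nt = int(round(pulse.trial_length / dt_ms))
    t = np.arange(nt) * dt_ms
    rate = peak_rate_hz * prof[:, None] * pulse_envelope(t, pulse)[None, :]
    counts = rng.poisson(rate * dt_ms / 1000.0)
    neuron_ids, bin_idx = np.nonzero(counts)
    reps = counts[neuron_ids, bin_idx]
    neuron_ids = np.repeat(neuron_ids, reps)
    bins = np.repeat(bin_idx, reps)
    times = (bins + rng.random(len(bins))) * dt_ms
    return SpikeRaster(n_neurons, pulse.trial_length, neuron_ids, times,
                       dict(meta or {}))
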