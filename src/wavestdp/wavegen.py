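"""Idealized plane-wave input activity.

Builds wave schedules (onset times, directions, speeds, inter-wave
intervals), turns them into per-neuron burst onset times, and generates
Bernoulli spike rasters on a 1 ms clock, optionally with background firing
and instantaneous nearest-neighbour correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kernels import BurstProfile, eval_burst

__all__ = [
    "InputLayer",
    "WaveEvent",
    "WaveSchedule",
    "SpikeRaster",
    "sample_lognormal",
    "sample_shifted_iwi",
    "build_schedule",
    "spikes_from_schedule",
]

DT = 0.001  # s; the simulation clock
MIN_WAVE_SPEED = 0.05  # mm/s floor for lognormal speeds


@dataclass(frozen=True)
class InputLayer:
    """Point input neurons on a regular 1D chain or 2D square lattice."""

    dims: int = 1
    n_per_axis: int = 500
    spacing: float = 0.02  # mm; 20 um chain default, use 0.034 for the RGC lattice

    def __post_init__(self) -> None:
        if self.dims not in (1, 2):
            raise ValueError("layer must be 1D or 2D")
        if self.spacing <= 0 or self.n_per_axis < 2:
            raise ValueError("invalid layer geometry")

    @property
    def n(self) -> int:
        return self.n_per_axis**self.dims

    @property
    def positions(self) -> np.ndarray:
        """(n,) positions in mm for 1D; (n, 2) row-major lattice for 2D,
        centred on the origin."""
        ax = (np.arange(self.n_per_axis) - (self.n_per_axis - 1) / 2.0) * self.spacing
        if self.dims == 1:
            return ax
        xx, yy = np.meshgrid(ax, ax, indexing="xy")
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def extent(self) -> float:
        return (self.n_per_axis - 1) * self.spacing


@dataclass(frozen=True)
class WaveEvent:
    t_start: float  # s; when the front enters the layer
    direction: tuple  # unit vector; (dx,) in 1D
    speed: float  # mm/s


@dataclass
class WaveSchedule:
    events: list  # of WaveEvent, onset-ordered
    layer: InputLayer

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_start": [e.t_start for e in self.events],
                "direction": [e.direction for e in self.events],
                "speed": [e.speed for e in self.events],
            }
        )


@dataclass
class SpikeRaster:
    """Bernoulli spike raster: at most one spike per neuron per 1 ms bin.

    ``bins``/``neurons`` are parallel arrays sorted by bin index.
    """

    bins: np.ndarray  # int64
    neurons: np.ndarray  # int32
    n_neurons: int
    duration: float  # s
    dt: float = DT

    def __post_init__(self) -> None:
        order = np.lexsort((self.neurons, self.bins))
        self.bins = np.asarray(self.bins, dtype=np.int64)[order]
        self.neurons = np.asarray(self.neurons, dtype=np.int32)[order]

    @property
    def spike_times(self) -> np.ndarray:
        return self.bins * self.dt

    @property
    def n_spikes(self) -> int:
        return len(self.bins)

    def times_for(self, neuron: int) -> np.ndarray:
        return self.bins[self.neurons == neuron] * self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron": self.neurons, "time_s": self.spike_times})

    def save(self, path: str | Path) -> None:
        df = self.to_frame()
        df.attrs = {}
        header = f"# n_neurons={self.n_neurons} duration={self.duration} dt={self.dt}\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SpikeRaster":
        with open(path) as fh:
            meta = dict(kv.split("=") for kv in fh.readline()[1:].split())
            df = pd.read_csv(fh)
        dt = float(meta["dt"])
        return cls(
            bins=np.round(df["time_s"].to_numpy() / dt).astype(np.int64),
            neurons=df["neuron"].to_numpy(np.int32),
            n_neurons=int(meta["n_neurons"]),
            duration=float(meta["duration"]),
            dt=dt,
        )


def sample_lognormal(
    mu: float, sigma: float, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Lognormal samples parameterized by their *linear* mean and SD.

    y = exp(m + s*z) with m = ln(mu / sqrt(1 + sigma^2/mu^2)) and
    s^2 = ln(1 + sigma^2/mu^2), so sample mean -> mu and sample SD -> sigma.
    sigma = 0 returns mu exactly.
    """
    if mu <= 0 or sigma < 0:
        raise ValueError("require mu > 0 and sigma >= 0")
    if sigma == 0:
        return np.full(n, mu)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    r2 = 1.0 + (sigma / mu) ** 2
    m = np.log(mu / np.sqrt(r2))
    s = np.sqrt(np.log(r2))
    return np.exp(m + s * rng.standard_normal(n))


def sample_shifted_iwi(
    mu: float, sigma: float, d: float, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Inter-wave intervals IWI = d + y with y lognormal of mean mu - d and
    SD sigma, guaranteeing successive waves never overlap a burst of
    duration d."""
    if mu <= d:
        raise ValueError("mean IWI must exceed the burst duration")
    return d + sample_lognormal(mu - d, sigma, n, rng)


def _directions_1d(n_waves: int, policy: str, rng: np.random.Generator) -> np.ndarray:
    if policy == "alternate":
        return np.where(np.arange(n_waves) % 2 == 0, 1.0, -1.0)
    if policy == "alternate_every_100":
        return np.where((np.arange(n_waves) // 100) % 2 == 0, 1.0, -1.0)
    if policy.startswith("random_of_"):
        # in 1D only two compass directions exist
        return rng.choice([1.0, -1.0], size=n_waves)
    raise ValueError(f"unknown direction policy {policy!r}")


def build_schedule(
    layer: InputLayer,
    n_waves: int,
    *,
    direction_policy: str = "alternate",
    speed: float = 3.0,
    speed_sigma: float = 0.0,
    iwi_mean: float | None = None,
    iwi_sigma: float = 1.0,
    burst_duration: float = 0.1,
    blank_gap: float = 5.0,
    n_directions: int = 16,
    seed: int | None = None,
) -> WaveSchedule:
    """Wave event list honouring gaps, direction policy, and sampled speeds/IWIs.

    Two scheduling regimes:
      * isolated waves (``iwi_mean=None``): the next wave starts one
        ``blank_gap`` after the previous wave's last burst has ended, letting
        postsynaptic activity decay to zero between waves;
      * overlapping waves (``iwi_mean`` set): onsets follow the shifted
        lognormal IWI distribution and the direction policy should be
        ``alternate_every_100`` (waves cannot clear the layer between onsets).

    Speeds are fixed when ``speed_sigma=0``, otherwise lognormal with mean
    ``speed``, SD ``speed_sigma``, floored at 0.05 mm/s.

    ``direction_policy='random_of_N'`` (2D) draws from ``n_directions``
    equally spaced compass angles starting at 0 degrees.
    """
    rng = np.random.default_rng(seed)
    if speed_sigma > 0:
        speeds = np.maximum(MIN_WAVE_SPEED, sample_lognormal(speed, speed_sigma, n_waves, rng))
    else:
        speeds = np.full(n_waves, float(speed))

    if layer.dims == 1:
        dirs = [(float(d),) for d in _directions_1d(n_waves, direction_policy, rng)]
    else:
        if direction_policy == "alternate":
            dirs = [((1.0, 0.0) if i % 2 == 0 else (-1.0, 0.0)) for i in range(n_waves)]
        elif direction_policy == "alternate_every_100":
            dirs = [((1.0, 0.0) if (i // 100) % 2 == 0 else (-1.0, 0.0)) for i in range(n_waves)]
        elif direction_policy.startswith("random_of_"):
            if n_directions not in (2, 4, 6, 16):
                raise ValueError("n_directions must be one of 2, 4, 6, 16")
            angles = 2.0 * np.pi * np.arange(n_directions) / n_directions
            picks = rng.integers(0, n_directions, size=n_waves)
            dirs = [(float(np.cos(angles[p])), float(np.sin(angles[p]))) for p in picks]
        else:
            raise ValueError(f"unknown direction policy {direction_policy!r}")

    events: list[WaveEvent] = []
    if iwi_mean is None:
        t = 0.0
        for i in range(n_waves):
            events.append(WaveEvent(t, dirs[i], speeds[i]))
            traversal = layer.extent * np.sqrt(layer.dims) / speeds[i] if layer.dims == 2 else layer.extent / speeds[i]
            t = t + traversal + burst_duration + blank_gap
    else:
        iwis = sample_shifted_iwi(iwi_mean, iwi_sigma, burst_duration, n_waves, rng)
        onsets = np.concatenate([[0.0], np.cumsum(iwis[:-1])])
        for i in range(n_waves):
            events.append(WaveEvent(float(onsets[i]), dirs[i], speeds[i]))
    return WaveSchedule(events=events, layer=layer)


def burst_onsets(layer: InputLayer, event: WaveEvent) -> np.ndarray:
    """Wavefront arrival time at each neuron: affine in position with slope
    1/speed along the propagation direction."""
    pos = layer.positions
    d = np.asarray(event.direction)
    proj = pos * d[0] if layer.dims == 1 else pos @ d
    return event.t_start + (proj - proj.min()) / event.speed


def spikes_from_schedule(
    layer: InputLayer,
    schedule: WaveSchedule,
    burst: BurstProfile,
    *,
    background_rate: float = 0.0,
    corr_strength: float = 0.0,
    seed: int | None = None,
    duration: float | None = None,
) -> SpikeRaster:
    """Generate the Bernoulli spike raster for a wave schedule.

    Stage 1 draws wave-burst spikes at rate R_in/(1+2c) (and background
    spikes, at rate R0/(1+2c), only in neurons not currently bursting);
    stage 2 adds a spike with probability c in each lattice neighbour of
    every stage-1 spiker, so realized rates stay at their nominal values
    while neighbours become instantaneously correlated.  One spike per
    neuron per bin.
    """
    c = corr_strength
    if not 0.0 <= c <= 1.0:
        raise ValueError("correlation strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = layer.n
    d = burst.duration
    scale = 1.0 / (1.0 + 2.0 * c)

    if duration is None:
        last = schedule.events[-1]
        duration = float(np.max(burst_onsets(layer, last)) + d + 1.0)
    n_bins = int(round(duration / DT))

    spike_bins: list[np.ndarray] = []
    spike_neurons: list[np.ndarray] = []
    burst_windows = []  # (neuron onsets, per event) for background exclusion

    for ev in schedule.events:
        onsets = burst_onsets(layer, ev)
        start_bins = np.round(onsets / DT).astype(np.int64)
        n_burst_bins = int(round(d / DT))
        rel = np.arange(n_burst_bins)
        if burst.shape == "boxcar":
            p = np.full(n_burst_bins, burst.rate * scale * DT)
        else:
            shape_vals = np.asarray(eval_burst(burst, rel * DT))
            # rescale so the expected count matches rate * duration
            shape_vals = shape_vals * (burst.rate * d / (shape_vals.sum() * DT + 1e-300))
            p = np.clip(shape_vals * scale * DT, 0.0, 1.0)
        if np.any(burst.rate * scale * DT > 1.0):
            p = np.clip(p, 0.0, 1.0)
        draws = rng.random((n, n_burst_bins)) < p[None, :]
        nrn, rb = np.nonzero(draws)
        bins = start_bins[nrn] + rel[rb]
        keep = bins < n_bins
        spike_bins.append(bins[keep])
        spike_neurons.append(nrn[keep].astype(np.int32))
        burst_windows.append((start_bins, n_burst_bins))

    if background_rate > 0.0:
        p_bg = background_rate * scale * DT
        counts = rng.binomial(n_bins, p_bg, size=n)
        bg_bins = []
        bg_nrn = []
        for j in range(n):
            if counts[j] == 0:
                continue
            b = rng.choice(n_bins, size=counts[j], replace=False)
            bg_bins.append(b)
            bg_nrn.append(np.full(counts[j], j, dtype=np.int32))
        if bg_bins:
            bgb = np.concatenate(bg_bins)
            bgn = np.concatenate(bg_nrn)
            # background is suppressed while a neuron is inside a wave burst
            in_burst = np.zeros(len(bgb), dtype=bool)
            for start_bins, nb in burst_windows:
                rel_b = bgb - start_bins[bgn]
                in_burst |= (rel_b >= 0) & (rel_b < nb)
            spike_bins.append(bgb[~in_burst])
            spike_neurons.append(bgn[~in_burst])

    bins = np.concatenate(spike_bins) if spike_bins else np.empty(0, dtype=np.int64)
    neurons = np.concatenate(spike_neurons) if spike_neurons else np.empty(0, dtype=np.int32)

    if c > 0.0 and len(bins):
        if layer.dims == 1:
            neigh = [(-1,), (1,)]
        else:
            neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        side = layer.n_per_axis
        extra_bins = []
        extra_nrn = []
        for off in neigh:
            if layer.dims == 1:
                tgt = neurons + off[0]
                valid = (tgt >= 0) & (tgt < side)
            else:
                row, col = neurons // side, neurons % side
                r2, c2 = row + off[1], col + off[0]
                valid = (r2 >= 0) & (r2 < side) & (c2 >= 0) & (c2 < side)
                tgt = r2 * side + c2
            hit = valid & (rng.random(len(bins)) < c)
            extra_bins.append(bins[hit])
            extra_nrn.append(tgt[hit].astype(np.int32))
        bins = np.concatenate([bins] + extra_bins)
        neurons = np.concatenate([neurons] + extra_nrn)

    # enforce at most one spike per neuron per bin
    key = bins * np.int64(n) + neurons
    _, unique_idx = np.unique(key, return_index=True)
    bins = bins[unique_idx]
    neurons = neurons[unique_idx]
    return SpikeRaster(bins=bins, neurons=neurons, n_neurons=n, duration=duration)
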