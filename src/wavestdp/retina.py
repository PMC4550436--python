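"""Complex retinal-wave generator: a SAC/RGC lattice model.

Starburst amacrine cells (SACs) on a 64x64 lattice (34 um spacing) excite
all SACs and retinal ganglion cells (RGCs) within 120 um.  Each cell carries
an excitation variable X that relaxes toward the number of currently active
presynaptic SACs with a 0.1 s decay constant.  A SAC whose excitation
crosses theta_S = 6 transmits for 1 s and then becomes refractory for a
normally distributed period (mean 40 s, SD 20 s, truncated at zero), after
which its excitation is reset to zero; spontaneous threshold crossings
(probability 0.0035 per SAC per 0.1 s step) seed new waves.  RGC crossings
of theta_R = 10 are logged as wave events.

Because the model's wave speed cannot be dialled directly, event times are
rescaled by a factor F_t <= 1 to compress the activity in time, and the
rescaled times drive 0.1 s, 50 Hz Bernoulli spike bursts in the RGCs, which
then serve as input neurons to the feedforward simulation.

On the discretization of the excitation dynamics: the model step equals the
decay constant (0.1 s), where a literal forward-Euler reading of the rate
equation leaves the excitation pinned at the instantaneous neighbour count
(at most 3.8 after scaling by the decay constant), which can never reach
the stated thresholds — waves could not exist.  The default integrator
instead accumulates the active-neighbour count each step under exponential
decay, X <- X e^(-dt/tau) + n, which preserves the stated decay constant,
makes the thresholds reachable, and produces the described regime of
recurring wavefronts winding between refractory domains.  'leaky'
(exponential relaxation toward n) and 'euler' variants are kept behind the
``integrator`` flag for comparison; neither nucleates collective waves at
the stated thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .kernels import BurstProfile
from .wavegen import DT, SpikeRaster

__all__ = ["RetinaParams", "WaveEventLog", "simulate_retina", "rescale_to_raster"]


@dataclass(frozen=True)
class RetinaParams:
    n_side: int = 64
    spacing: float = 0.034  # mm
    coupling_radius: float = 0.120  # mm
    tau: float = 0.1  # s, excitation decay constant
    dt: float = 0.1  # s, model step
    theta_sac: float = 6.0
    theta_rgc: float = 10.0
    transmit_duration: float = 1.0  # s a SAC stays active
    refractory_mean: float = 40.0  # s
    refractory_sd: float = 20.0  # s
    spontaneous_p: float = 0.0035  # per SAC per step


@dataclass
class WaveEventLog:
    """Per-RGC threshold-crossing times, on the 0.1 s model clock."""

    times: np.ndarray  # s, event times
    rgc: np.ndarray  # flat RGC index per event
    n_side: int
    spacing: float
    duration: float

    @property
    def n_events(self) -> int:
        return len(self.times)


def _coupling_matrix(p: RetinaParams) -> sparse.csr_matrix:
    n = p.n_side
    ax = np.arange(n)
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    pos = np.column_stack([xx.ravel(), yy.ravel()]) * p.spacing
    r = p.coupling_radius / p.spacing
    rad = int(np.floor(r))
    offsets = [
        (dx, dy)
        for dx in range(-rad, rad + 1)
        for dy in range(-rad, rad + 1)
        if (dx, dy) != (0, 0) and dx * dx + dy * dy <= r * r
    ]
    rows, cols = [], []
    col_idx = np.arange(n * n)
    cx, cy = col_idx % n, col_idx // n
    for dx, dy in offsets:
        tx, ty = cx + dx, cy + dy
        ok = (tx >= 0) & (tx < n) & (ty >= 0) & (ty < n)
        rows.append((ty[ok] * n + tx[ok]))
        cols.append(col_idx[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(n * n, n * n))


def coupling_info(p: RetinaParams = RetinaParams()) -> dict:
    """Audit helper: the symmetric SAC coupling graph and its degree stats."""
    A = _coupling_matrix(p)
    deg = np.asarray(A.sum(axis=1)).ravel()
    return {"matrix": A, "max_in_degree": int(deg.max()), "min_in_degree": int(deg.min())}


def simulate_retina(
    duration: float,
    seed: int = 0,
    params: RetinaParams | None = None,
    integrator: str = "accumulate",
    record_movie: bool = False,
) -> WaveEventLog | tuple[WaveEventLog, np.ndarray]:
    """Run the SAC/RGC model for ``duration`` seconds of model time.

    Returns the log of RGC upward threshold crossings.  ``integrator``:
    'accumulate' (default: excitation increments by the active-neighbour
    count each step and decays exponentially), 'leaky' (exponential
    relaxation toward the neighbour count), or 'euler' (forward Euler of the
    relaxation dynamics).
    With ``record_movie`` the boolean SAC-active history is also returned
    (for diagnostics; memory scales with duration).
    """
    p = params or RetinaParams()
    if integrator not in ("leaky", "euler", "accumulate"):
        raise ValueError(f"unknown integrator {integrator!r}")
    rng = np.random.default_rng(seed)
    A = _coupling_matrix(p)
    N = p.n_side * p.n_side
    n_steps = int(round(duration / p.dt))
    transmit_steps = int(round(p.transmit_duration / p.dt))

    X_s = np.zeros(N)
    X_r = np.zeros(N)
    active_left = np.zeros(N, dtype=np.int64)  # steps of transmission left
    refr_left = np.zeros(N, dtype=np.int64)  # refractory steps left
    decay = np.exp(-p.dt / p.tau)
    gain = 1.0 - decay

    ev_t: list[np.ndarray] = []
    ev_i: list[np.ndarray] = []
    movie = np.zeros((n_steps, N), dtype=bool) if record_movie else None
    _above_prev = np.zeros(N, dtype=bool)

    for step in range(n_steps):
        active = active_left > 0
        n_act = A @ active.astype(np.float64)

        if integrator == "leaky":
            X_s = X_s * decay + n_act * gain
            X_r = X_r * decay + n_act * gain
        elif integrator == "euler":
            X_s = X_s + (p.dt / p.tau) * (n_act - X_s)
            X_r = X_r + (p.dt / p.tau) * (n_act - X_r)
        else:  # accumulate
            X_s = X_s * decay + n_act
            X_r = X_r * decay + n_act

        # RGC upward crossings (no RGC refractoriness)
        crossed = (X_r > p.theta_rgc) & ~_above_prev
        idx = np.nonzero(crossed)[0]
        if len(idx):
            ev_t.append(np.full(len(idx), (step + 1) * p.dt))
            ev_i.append(idx)
        _above_prev[:] = X_r > p.theta_rgc

        # SAC activation: eligible cells crossing threshold or spontaneous
        eligible = (~active) & (refr_left == 0)
        fire = eligible & (X_s > p.theta_sac)
        spont = eligible & (rng.random(N) < p.spontaneous_p)
        newly = fire | spont
        active_left[newly] = transmit_steps

        # transmission countdown; entering refractoriness when it ends
        ending = active & (active_left == 1)
        active_left[active] -= 1
        n_end = int(ending.sum())
        if n_end:
            dur = np.maximum(0.0, rng.normal(p.refractory_mean, p.refractory_sd, n_end))
            refr_left[ending] = np.maximum(1, np.round(dur / p.dt).astype(np.int64))
        leaving = refr_left == 1
        refr_left[refr_left > 0] -= 1
        X_s[leaving] = 0.0  # excitation reset at the end of refractoriness

        if record_movie:
            movie[step] = active

    log = WaveEventLog(
        times=np.concatenate(ev_t) if ev_t else np.empty(0),
        rgc=np.concatenate(ev_i).astype(np.int64) if ev_i else np.empty(0, dtype=np.int64),
        n_side=p.n_side,
        spacing=p.spacing,
        duration=duration,
    )
    if record_movie:
        return log, movie.reshape(n_steps, p.n_side, p.n_side)
    return log


def rescale_to_raster(
    log: WaveEventLog,
    F_t: float,
    burst: BurstProfile | None = None,
    seed: int = 0,
) -> SpikeRaster:
    """Compress RGC event times by F_t and emit Bernoulli burst spikes.

    Each rescaled event starts a 0.1 s, 50 Hz burst (1 ms precision) for its
    RGC; overlapping rescaled bursts of one RGC are merged into the union of
    their windows so the one-spike-per-bin contract holds.
    """
    if not 0.0 < F_t <= 1.0:
        raise ValueError("temporal rescaling factor must lie in (0, 1]")
    burst = burst or BurstProfile("boxcar", 50.0, 0.1)
    rng = np.random.default_rng(seed)
    n = log.n_side * log.n_side
    duration = log.duration * F_t + burst.duration
    n_bins = int(np.ceil(duration / DT))
    burst_bins = int(round(burst.duration / DT))
    p_spike = burst.rate * DT

    onset_bins = np.round(log.times * F_t / DT).astype(np.int64)
    order = np.lexsort((onset_bins, log.rgc))
    rgc_sorted = log.rgc[order]
    onset_sorted = onset_bins[order]

    bins_out: list[np.ndarray] = []
    nrn_out: list[np.ndarray] = []
    # merge each RGC's overlapping burst windows, then draw Bernoulli spikes
    i = 0
    n_ev = len(rgc_sorted)
    while i < n_ev:
        j = i
        cell = rgc_sorted[i]
        while j < n_ev and rgc_sorted[j] == cell:
            j += 1
        starts = onset_sorted[i:j]
        win_start = starts[0]
        win_end = starts[0] + burst_bins
        windows = []
        for s in starts[1:]:
            if s <= win_end:
                win_end = max(win_end, s + burst_bins)
            else:
                windows.append((win_start, win_end))
                win_start, win_end = s, s + burst_bins
        windows.append((win_start, win_end))
        for a, b in windows:
            b = min(b, n_bins)
            if b <= a:
                continue
            hits = np.nonzero(rng.random(b - a) < p_spike)[0]
            if len(hits):
                bins_out.append(a + hits)
                nrn_out.append(np.full(len(hits), cell, dtype=np.int32))
        i = j

    bins = np.concatenate(bins_out) if bins_out else np.empty(0, dtype=np.int64)
    nrn = np.concatenate(nrn_out) if nrn_out else np.empty(0, dtype=np.int32)
    return SpikeRaster(bins=bins, neurons=nrn, n_neurons=n, duration=duration)
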