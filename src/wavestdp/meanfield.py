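"""Deterministic weight dynamics: forward-Euler integration of dw/dT = eta kappa * w.

This is the noise-free counterpart of the spiking simulation.  The same
nonlinearities are applied: hard bounds on weights at [0, 1], alternation of
the wave direction (kernel mirrored on odd steps), and an arbor mask that
multiplies the weight derivative.  Convolution uses zero padding — the layer
is embedded in a silent surround, as waves enter and leave a finite layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import oaconvolve

from .kernels import BurstProfile, EPSPKernel, STDPRule
from .theory import DEFAULT_RESOLUTION, SpatialKernel, build_kappa

__all__ = [
    "ArborSpec",
    "WeightField",
    "init_weights",
    "integrate",
    "integrate_2d",
    "growth_rate",
    "classify_rf",
    "rf_phase_space",
]


@dataclass(frozen=True)
class ArborSpec:
    """Hard spatial mask: synapses farther than ``radius`` from ``center``
    are disconnected and never updated."""

    center: float = 0.0
    radius: float = 0.4

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("arbor radius must be positive")

    def mask(self, positions: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(positions) - self.center) <= self.radius


@dataclass
class WeightField:
    """Synaptic strengths w(x) in [0, 1] on a uniform lattice, with history."""

    positions: np.ndarray  # mm; (n,) in 1D or (n, dims) for a flattened lattice
    w: np.ndarray
    eta: float = 1e-3
    arbor: np.ndarray | None = None  # boolean mask, True inside the arbor
    history: list = field(default_factory=list)  # [(T, w snapshot)]

    @property
    def spacing(self) -> float:
        p = self.positions
        if p.ndim == 1:
            return float(p[1] - p[0])
        return float(np.min(np.linalg.norm(np.diff(np.unique(p[:, 0]))[None])) or 0.0)

    def snapshot(self, T: float) -> None:
        if self.history and T <= self.history[-1][0]:
            raise ValueError("history times must be strictly increasing")
        self.history.append((T, self.w.copy()))


def init_weights(
    n: int,
    spacing: float,
    mode: str = "uniform_half",
    rf0: float | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    eta: float = 1e-3,
) -> WeightField:
    """Initial synaptic strengths on an n-site chain centred at x = 0.

    ``uniform_half``: every weight 0.5 (plus optional Gaussian noise, needed
    to seed pattern growth in noise-free mean-field runs).  ``rf_block``: the
    central block of round(rf0 / spacing) synapses at 1.0, the rest at 0.0 —
    a coarse initial receptive field.  Values are clipped to [0, 1].
    """
    positions = (np.arange(n) - (n - 1) / 2.0) * spacing
    if mode == "uniform_half":
        w = np.full(n, 0.5)
    elif mode == "rf_block":
        if rf0 is None:
            raise ValueError("rf_block initialization requires rf0")
        m = int(round(rf0 / spacing))
        if m > n:
            raise ValueError("initial RF larger than the layer")
        w = np.zeros(n)
        start = (n - m) // 2
        w[start : start + m] = 1.0
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise_sd, size=n)
    return WeightField(positions=positions, w=np.clip(w, 0.0, 1.0), eta=eta)


def _kernel_on_lattice(kernel: SpatialKernel, spacing: float) -> np.ndarray:
    _, vals = kernel.resampled(spacing)
    return vals


def growth_rate(kernel: SpatialKernel, spacing: float, k: float) -> complex:
    """kappa~(k) evaluated from the kernel as resampled on the weight lattice.

    This is the eigenvalue governing the linear-regime growth of the weight
    mode at spatial frequency k: |w~(k, T)| = |w~(k, 0)| exp(eta Re[kappa~] T).
    """
    xs, vals = kernel.resampled(spacing)
    return complex(np.sum(vals * np.exp(-2j * np.pi * k * xs)) * spacing)


def integrate(
    field: WeightField,
    kernel: SpatialKernel,
    n_steps: int,
    dt_T: float | None = None,
    alternate: bool = True,
    arbor: ArborSpec | None = None,
    snapshot_every: int = 0,
    safety: float = 0.1,
) -> WeightField:
    """Forward-Euler integration of the weight field under kernel ``kernel``.

    Per step: dw = eta * dt_T * (kappa * w), with the kernel mirrored in x on
    odd steps when ``alternate`` (waves run back and forth); the arbor mask
    multiplies dw; weights are clipped to [0, 1].  When ``dt_T`` is omitted
    it is chosen so that eta * dt_T * max|kappa~| = ``safety``, which keeps
    the explicit scheme stable.
    """
    w = field.w
    if w.ndim != 1:
        raise ValueError("mean-field integration operates on 1D weight fields")
    spacing = float(field.positions[1] - field.positions[0])
    kv = _kernel_on_lattice(kernel, spacing)
    # spectral radius estimate for the stability bound
    kmax = float(np.max(np.abs(np.fft.rfft(kv, n=4 * len(kv))))) * spacing
    if dt_T is None:
        dt_T = safety / (field.eta * kmax)
    elif field.eta * dt_T * kmax > 1.0:
        raise ValueError(
            f"unstable step: eta*dt_T*max|kappa~| = {field.eta * dt_T * kmax:.3g} > 1"
        )
    mask = arbor.mask(field.positions) if arbor is not None else None
    if mask is not None:
        w = np.where(mask, w, 0.0)
    kv_rev = kv[::-1]
    T = field.history[-1][0] if field.history else 0.0
    if not field.history:
        field.snapshot(0.0)
    for step in range(n_steps):
        kern = kv_rev if (alternate and step % 2 == 1) else kv
        dw = field.eta * dt_T * oaconvolve(w, kern, mode="same") * spacing
        if np.max(np.abs(dw)) > 0.5:
            raise ValueError("integration unstable: |dw| > 0.5 in one step; reduce dt_T")
        if mask is not None:
            dw = np.where(mask, dw, 0.0)
        w = np.clip(w + dw, 0.0, 1.0)
        T += dt_T
        if snapshot_every and (step + 1) % snapshot_every == 0:
            field.w = w
            field.snapshot(T)
    field.w = w
    if not snapshot_every:
        field.snapshot(T)
    return field


def integrate_2d(
    w: np.ndarray,
    kernel: SpatialKernel,
    n_steps: int,
    *,
    axis: str = "x",
    spacing: float = 0.02,
    eta: float = 1e-3,
    dt_T: float | None = None,
    alternate: bool = True,
    arbor_mask: np.ndarray | None = None,
    safety: float = 0.1,
) -> np.ndarray:
    """Weight dynamics on a 2D lattice under an axis-aligned plane wave.

    A plane wave interacts only along its propagation axis (the wavefront
    is simultaneous along the orthogonal axis, i.e. infinitely fast there,
    frequency zero), so the 1D kernel is applied along ``axis`` ('x' =
    columns, 'y' = rows) and the field is left uncoupled orthogonally.
    Bounds, alternation, and an optional boolean arbor mask behave as in
    :func:`integrate`.
    """
    if w.ndim != 2:
        raise ValueError("integrate_2d expects a 2D weight lattice")
    conv_axis = 1 if axis == "x" else 0
    kv = _kernel_on_lattice(kernel, spacing)
    kmax = float(np.max(np.abs(np.fft.rfft(kv, n=4 * len(kv))))) * spacing
    if dt_T is None:
        dt_T = safety / (eta * kmax)
    kern_f = kv[None, :] if conv_axis == 1 else kv[:, None]
    kern_b = kern_f[::-1, ::-1]
    out = w.copy()
    if arbor_mask is not None:
        out = np.where(arbor_mask, out, 0.0)
    for step in range(n_steps):
        kern = kern_b if (alternate and step % 2 == 1) else kern_f
        dw = eta * dt_T * oaconvolve(out, kern, mode="same") * spacing
        if arbor_mask is not None:
            dw = np.where(arbor_mask, dw, 0.0)
        out = np.clip(out + dw, 0.0, 1.0)
    return out


def classify_rf(
    w: np.ndarray, spacing: float, threshold: float = 0.5
) -> tuple[int, float]:
    """Number of contiguous supra-threshold regions and their total extent (mm)."""
    strong = np.asarray(w) > threshold
    n_strong = int(strong.sum())
    if n_strong == 0:
        return 0, 0.0
    edges = np.diff(strong.astype(int))
    n_regions = int((edges == 1).sum()) + int(strong[0])
    return n_regions, n_strong * spacing


def rf_phase_space(
    rf0: float,
    v_list: Sequence[float],
    tau_list: Sequence[float],
    rule_template: Callable[[float], STDPRule],
    burst: BurstProfile | None,
    epsp: EPSPKernel | None,
    *,
    spacing: float = 0.02,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_steps: int = 600,
    eta: float = 1e-3,
    resolution: float | None = None,
) -> dict:
    """Refinement phase space: final RF mode and size over (v, tau_plus).

    Each cell integrates the mean-field dynamics from an rf_block start under
    an arbor of width max(0.8 mm, rf0 + 0.4 mm).  The final field is
    classified by its contiguous regions of weights > 0.5: one region smaller
    than rf0 = 'contract', one region larger = 'expand', two or more =
    'split' ('none' if no weight stays above threshold).  A cell whose
    weights are still moving at the step budget is flagged, not raised.
    """
    arbor_width = max(0.8, rf0 + 0.4)
    arbor = ArborSpec(center=0.0, radius=arbor_width / 2.0)
    n = int(np.ceil(2.0 * arbor_width / spacing)) | 1
    shape = (len(v_list), len(tau_list))
    modes = np.empty(shape, dtype=object)
    final_size = np.zeros(shape)
    pct_change = np.zeros(shape)
    converged = np.ones(shape, dtype=bool)
    for i, v in enumerate(v_list):
        for j, tp in enumerate(tau_list):
            rule = rule_template(tp)
            if resolution is None:
                d = burst.duration if burst is not None else 0.0
                scale = (rule.tau_minus + d) * v
                res = min(max(scale / 2000.0, DEFAULT_RESOLUTION), spacing / 4.0)
                if epsp is not None:
                    res = min(res, epsp.tau_d * v)
            else:
                res = resolution
            # snap so the synapse lattice is an integer multiple of the grid
            res = spacing / int(np.ceil(spacing / res))
            kern = build_kappa(rule, burst, epsp, v, resolution=res)
            fld = init_weights(
                n, spacing, "rf_block", rf0=rf0, noise_sd=noise_sd, seed=seed, eta=eta
            )
            w_prev = None
            integrate(fld, kern, n_steps, alternate=True, arbor=arbor)
            w_prev = fld.history[-1][1] if len(fld.history) > 1 else None
            # convergence probe: one more short leg must not change the RF set
            integrate(fld, kern, 20, alternate=True, arbor=arbor)
            n_reg, size = classify_rf(fld.w, spacing)
            if w_prev is not None:
                converged[i, j] = np.array_equal(fld.w > 0.5, w_prev > 0.5)
            final_size[i, j] = size
            pct_change[i, j] = 100.0 * (size - rf0) / rf0
            if n_reg == 0:
                modes[i, j] = "none"
            elif n_reg >= 2:
                modes[i, j] = "split"
            else:
                modes[i, j] = "contract" if size < rf0 else "expand"
    return {
        "v": np.asarray(v_list, dtype=float),
        "tau_plus": np.asarray(tau_list, dtype=float),
        "mode": modes,
        "final_size": final_size,
        "pct_change": pct_change,
        "converged": converged,
    }
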