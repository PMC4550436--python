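"""Temporal kernels: STDP pairing rules, input burst profiles, EPSP waveform.

All times are in seconds, rates in Hz.  The pairing-time convention is
``dt = t_in - t_out`` throughout the package: an input (presynaptic) spike
that precedes an output (postsynaptic) spike has ``dt < 0`` and, for the
asymmetric rule, strengthens the synapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPRule",
    "BurstProfile",
    "EPSPKernel",
    "eval_stdp",
    "stdp_integral",
    "eval_burst",
    "eval_epsp",
    "epsp_peak_time",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class STDPRule:
    """A parametric spike-pairing rule K(dt).

    ``asymmetric``: exponential strengthening lobe for dt < 0, exponential
    weakening lobe for dt > 0, zero at dt = 0.
    ``symmetric``: difference of two zero-centred Gaussians (Mexican-hat-like
    when the weakening Gaussian is wider).
    """

    shape: str
    A_plus: float
    A_minus: float
    tau_plus: float
    tau_minus: float

    def __post_init__(self) -> None:
        if self.shape not in ("asymmetric", "symmetric"):
            raise ValueError(f"unknown STDP shape {self.shape!r}")
        if not (self.tau_plus > 0 and self.tau_minus > 0):
            raise ValueError("STDP time constants must be positive")
        if self.A_plus < 0 or self.A_minus < 0:
            raise ValueError("STDP amplitudes must be non-negative")

    @classmethod
    def asymmetric(
        cls,
        tau_plus: float = 0.020,
        tau_minus: float | None = None,
        A_plus: float = 1.0,
        A_minus: float = 0.51,
    ) -> "STDPRule":
        """Asymmetric rule; defaults tau_minus = 2 tau_plus, A+ = 1, A- = 0.51."""
        if tau_minus is None:
            tau_minus = 2.0 * tau_plus
        return cls("asymmetric", A_plus, A_minus, tau_plus, tau_minus)

    @classmethod
    def symmetric(
        cls,
        tau_plus: float = 0.020,
        tau_minus: float | None = None,
        A_plus: float = 3.2,
        A_minus: float = 2.1,
    ) -> "STDPRule":
        """Symmetric rule; defaults tau_minus = 1.6 tau_plus, A+ = 3.2, A- = 2.1."""
        if tau_minus is None:
            tau_minus = 1.6 * tau_plus
        return cls("symmetric", A_plus, A_minus, tau_plus, tau_minus)


@dataclass(frozen=True)
class BurstProfile:
    """Firing-rate profile of the wave-related burst.

    ``boxcar``: rate R_in for 0 <= t < d, else 0.
    ``alpha``: (t/d) exp(-t/d) shape, rescaled so that its time integral
    equals R_in * d (same expected spike count as the boxcar).
    """

    shape: str = "boxcar"
    rate: float = 50.0
    duration: float = 0.1

    def __post_init__(self) -> None:
        if self.shape not in ("boxcar", "alpha"):
            raise ValueError(f"unknown burst shape {self.shape!r}")
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("burst rate and duration must be positive")


@dataclass(frozen=True)
class EPSPKernel:
    """Unit-integral difference-of-exponentials EPSP, AMPA-like by default."""

    tau_d: float = 0.005
    tau_r: float = 0.001

    def __post_init__(self) -> None:
        if not (self.tau_d > self.tau_r > 0):
            raise ValueError("EPSP requires tau_d > tau_r > 0")


def eval_stdp(rule: STDPRule, dt: np.ndarray | float) -> np.ndarray | float:
    """Evaluate K(dt) with the convention dt = t_in - t_out.

    Vectorized over arrays of pairing intervals.  Raises on non-finite dt.
    """
    dt_arr = np.asarray(dt, dtype=float)
    if not np.all(np.isfinite(dt_arr)):
        raise ValueError("pairing intervals must be finite")
    if rule.shape == "asymmetric":
        out = np.where(
            dt_arr < 0,
            rule.A_plus * np.exp(dt_arr / rule.tau_plus),
            -rule.A_minus * np.exp(-dt_arr / rule.tau_minus),
        )
        out = np.where(dt_arr == 0, 0.0, out)
    else:
        out = rule.A_plus * np.exp(-0.5 * (dt_arr / rule.tau_plus) ** 2) - (
            rule.A_minus * np.exp(-0.5 * (dt_arr / rule.tau_minus) ** 2)
        )
    if np.isscalar(dt) or np.ndim(dt) == 0:
        return float(out)
    return out


def stdp_sample(rule: STDPRule, dt: np.ndarray | float) -> np.ndarray | float:
    """K(dt) sampled for quadrature / kernel construction.

    Identical to :func:`eval_stdp` except that, for the asymmetric rule, the
    dt = 0 sample takes the mean of the one-sided limits, (A+ - A-)/2, so
    that grid sums converge to the true integral despite the jump.
    """
    out = eval_stdp(rule, dt)
    if rule.shape == "asymmetric":
        mid = 0.5 * (rule.A_plus - rule.A_minus)
        if np.ndim(out) == 0:
            return mid if np.asarray(dt) == 0 else out
        out = np.where(np.asarray(dt) == 0, mid, out)
    return out


def stdp_integral(rule: STDPRule) -> float:
    """Closed-form integral of K over all pairing intervals.

    This is the DC value of the spatially mapped kernel and controls the net
    strengthening/weakening bias of the rule.
    """
    if rule.shape == "asymmetric":
        return rule.A_plus * rule.tau_plus - rule.A_minus * rule.tau_minus
    return _SQRT_2PI * (rule.A_plus * rule.tau_plus - rule.A_minus * rule.tau_minus)


def eval_burst(profile: BurstProfile, t: np.ndarray | float) -> np.ndarray | float:
    """Burst profile at time t after burst onset.

    Boxcar: the firing rate R_in (Hz) on [0, d).  Alpha: the raw shape
    (t/d) exp(-t/d), which peaks at exp(-1) at t = d; when used to generate
    spikes or build the spatial kernel it is rescaled by the rate so that
    its integral equals R_in * d, matching the boxcar's expected spike count.
    """
    t_arr = np.asarray(t, dtype=float)
    if profile.shape == "boxcar":
        out = np.where((t_arr >= 0) & (t_arr < profile.duration), profile.rate, 0.0)
    else:
        d = profile.duration
        out = np.where(t_arr >= 0, (t_arr / d) * np.exp(-np.clip(t_arr, 0, None) / d), 0.0)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def eval_epsp(kernel: EPSPKernel, t_since_spike: np.ndarray | float) -> np.ndarray | float:
    """EPSP waveform (units 1/s; integrates to one) at t after the input spike."""
    if kernel.tau_d == kernel.tau_r:
        raise ValueError("degenerate EPSP kernel: tau_d == tau_r")
    t_arr = np.asarray(t_since_spike, dtype=float)
    tc = np.clip(t_arr, 0.0, None)
    out = np.where(
        t_arr >= 0,
        (np.exp(-tc / kernel.tau_d) - np.exp(-tc / kernel.tau_r))
        / (kernel.tau_d - kernel.tau_r),
        0.0,
    )
    if np.isscalar(t_since_spike) or np.ndim(t_since_spike) == 0:
        return float(out)
    return out


def epsp_peak_time(kernel: EPSPKernel) -> float:
    """Time of the EPSP maximum: (tau_d tau_r / (tau_d - tau_r)) ln(tau_d/tau_r)."""
    td, tr = kernel.tau_d, kernel.tau_r
    return td * tr / (td - tr) * np.log(td / tr)
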