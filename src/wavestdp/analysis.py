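"""Quantification of connectivity patterns and complex wave movies.

Dominant-frequency estimation of weight fields (power spectrum with the DC
component removed, single-Gaussian peak fit), the spectral-concentration
robustness statistic Psi_w, receptive-field size metrics, centre-of-mass
(COM) tracking of individual waves in rate movies, and the visual-angle to
retinal-distance conversion R = pi * r * A / 135.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .wavegen import SpikeRaster

__all__ = [
    "SpectrumFit",
    "WaveTrack",
    "dominant_frequency",
    "robustness",
    "rf_metrics",
    "raster_to_movie",
    "track_waves",
    "angle_to_distance",
    "distance_to_angle",
    "EYE_RADII",
]

#: eyeball radii in mm for the conversion presets
EYE_RADII = {
    "mouse_neonatal": 1.1,
    "mouse_adult": 1.7,
    "ferret_eye_opening": 2.8,
    "cat_4wk": 5.0,
}


@dataclass
class SpectrumFit:
    k: np.ndarray  # cycles/mm, positive frequencies
    power: np.ndarray  # |w~(k)|^2, DC removed
    dominant_k: float  # centre of the fitted Gaussian (or argmax fallback)
    amplitude: float
    width: float
    converged: bool
    residual: float


@dataclass
class WaveTrack:
    wave_id: int
    t: np.ndarray  # s, bin centres of the retained trajectory
    com: np.ndarray  # (len(t), 2) positions in mm
    n_spacetime_bins: int
    path_length: float  # mm
    duration: float  # s
    speed: float  # mm/s
    mean_com: np.ndarray  # time-averaged COM (mm), used for the edge filter


def _gauss(k, a, c, s):
    return a * np.exp(-0.5 * ((k - c) / s) ** 2)


def dominant_frequency(weights: np.ndarray, spacing: float) -> SpectrumFit:
    """Dominant spatial frequency of a 1D weight field.

    The mean is subtracted (DC removal), the positive-frequency power
    spectrum computed, and a single offset-free Gaussian least-squares
    fitted, initialized at the argmax bin; the dominant frequency is the
    fitted centre.  If the fit fails the argmax bin is reported and the
    result flagged unconverged.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) < 32:
        raise ValueError("need a 1D field of at least 32 weights")
    P = np.abs(np.fft.rfft(w - w.mean())) ** 2
    k = np.fft.rfftfreq(len(w), d=spacing)
    k, P = k[1:], P[1:]
    if P.max() == 0:
        return SpectrumFit(k, P, np.nan, 0.0, np.nan, False, 0.0)
    i = int(np.argmax(P))
    try:
        popt, _ = curve_fit(
            _gauss,
            k,
            P,
            p0=[P[i], k[i], max(2.0 * (k[1] - k[0]), 0.05)],
            bounds=([0.0, k[0], (k[1] - k[0]) / 4.0], [np.inf, k[-1], k[-1]]),
            maxfev=10000,
        )
        resid = float(np.sum((P - _gauss(k, *popt)) ** 2))
        return SpectrumFit(k, P, float(popt[1]), float(popt[0]), float(popt[2]), True, resid)
    except Exception:
        return SpectrumFit(k, P, float(k[i]), float(P[i]), np.nan, False, np.nan)


def robustness(
    weights: np.ndarray,
    spacing: float,
    k_star_hint: float | None = None,
    reference_psi: float | None = None,
) -> dict:
    """Spectral-concentration robustness Psi_w of a connectivity pattern.

    Psi_w = P(k_dom) / sum_i P(k_i), the sum over the discrete spectrum from
    -k_N to k_N with the DC bin removed.  The dominant bin is the bin nearest
    ``k_star_hint`` when given (concentration at the *predicted* frequency),
    else the empirical argmax.  A noiseless single-frequency field gives 0.5
    (the +/-k pair splits the power).  ``reference_psi`` divides the raw
    value for reporting relative to a reference condition.
    """
    w = np.asarray(weights, dtype=float)
    P = np.abs(np.fft.rfft(w - w.mean())) ** 2
    k = np.fft.rfftfreq(len(w), d=spacing)
    # full-spectrum total: positive bins count twice (+k and -k), except any
    # exact Nyquist bin which exists once
    double = np.full(len(P), 2.0)
    double[0] = 0.0
    if len(w) % 2 == 0:
        double[-1] = 1.0
    total = float(np.sum(P * double))
    if total == 0:
        raise ValueError("zero total spectral power")
    if k_star_hint is not None:
        i = 1 + int(np.argmin(np.abs(k[1:] - k_star_hint)))
    else:
        i = 1 + int(np.argmax(P[1:]))
    psi = float(P[i] / total)
    out = {"psi": psi, "k_dominant": float(k[i])}
    if reference_psi is not None:
        out["psi_referenced"] = psi / reference_psi
    return out


def rf_metrics(weights: np.ndarray, spacing: float, threshold: float = 0.5) -> dict:
    """Receptive-field size metrics from a weight field.

    1D: number of strong synapses (> threshold), their extent in mm, and the
    number of contiguous subfields.  2D: strong-synapse count, area in mm^2
    (count times spacing squared), and 8-connected subfield count.
    """
    w = np.asarray(weights, dtype=float)
    strong = w > threshold
    n_strong = int(strong.sum())
    if w.ndim == 1:
        if n_strong == 0:
            n_sub = 0
        else:
            edges = np.diff(strong.astype(int))
            n_sub = int((edges == 1).sum()) + int(strong[0])
        return {
            "n_strong": n_strong,
            "size_mm": n_strong * spacing,
            "n_subfields": n_sub,
        }
    if w.ndim == 2:
        structure = np.ones((3, 3), dtype=int)
        _, n_sub = ndimage.label(strong, structure=structure)
        return {
            "n_strong": n_strong,
            "area_mm2": n_strong * spacing**2,
            "n_subfields": int(n_sub),
        }
    raise ValueError("weights must be 1D or 2D")


def raster_to_movie(
    raster: SpikeRaster, n_side: int, bin_s: float = 0.1, duration: float | None = None
) -> np.ndarray:
    """Firing-rate movie (n_side, n_side, n_tbins) in Hz from a lattice raster.

    Neuron j sits at row j // n_side, column j % n_side; each time bin holds
    spikes / bin_s.
    """
    duration = duration if duration is not None else raster.duration
    n_t = int(np.ceil(duration / bin_s))
    movie = np.zeros((n_side * n_side, n_t), dtype=np.float32)
    tb = (raster.bins * raster.dt / bin_s).astype(np.int64)
    ok = tb < n_t
    np.add.at(movie, (raster.neurons[ok], tb[ok]), 1.0)
    movie /= bin_s
    return movie.reshape(n_side, n_side, n_t)


def track_waves(
    movie: np.ndarray,
    spacing: float = 0.034,
    bin_s: float = 0.1,
    *,
    smooth_sigma_space: float = 0.034,
    smooth_sigma_time: float = 0.1,
    rate_floor: float = 10.0,
    merge_radius: float = 0.680,
    min_duration: float = 0.5,
    min_spacetime_bins: int = 1000,
    edge_margin: int = 10,
    com_smooth_sigma: float = 0.1,
) -> list[WaveTrack]:
    """Isolate individual waves in a rate movie by centre-of-mass tracking.

    Pipeline: Gaussian-smooth the movie (sigma 34 um in space, 100 ms in
    time), zero pixels below ``rate_floor``, find 8-connected active domains
    in each time bin, compute each domain's COM weighting by the *unsmoothed*
    rates inside the domain boundary, then link IDs: domains in the same bin
    with COMs closer than 680 um share an ID, and a domain inherits the ID
    of any previous-bin COM within 680 um.  Each track's COM trajectory is
    zero-padded, Gaussian-smoothed in time (SD 0.1 s), and its first and
    last two points discarded.  Tracks are retained only if they last longer
    than ``min_duration``, cover at least ``min_spacetime_bins`` space-time
    bins, and keep their time-averaged COM out of the outer ``edge_margin``
    cells.  Speed = COM path length / trajectory duration.
    """
    if movie.ndim != 3:
        raise ValueError("movie must be (ny, nx, nt)")
    if np.any(movie < 0):
        raise ValueError("rate movie must be non-negative")
    ny, nx, nt = movie.shape
    sig_px = smooth_sigma_space / spacing
    sig_tb = smooth_sigma_time / bin_s
    smoothed = ndimage.gaussian_filter(
        movie.astype(np.float32), sigma=(sig_px, sig_px, sig_tb), mode="constant"
    )
    smoothed[smoothed < rate_floor] = 0.0

    structure = np.ones((3, 3), dtype=int)
    merge_px = merge_radius / spacing

    next_id = 0
    # per time bin: {wave_id: (com_yx_px, mass, n_pixels)}
    prev: dict[int, np.ndarray] = {}
    tracks: dict[int, dict] = {}

    for t in range(nt):
        frame = smoothed[:, :, t]
        labels, n_dom = ndimage.label(frame > 0, structure=structure)
        if n_dom == 0:
            prev = {}
            continue
        raw = movie[:, :, t]
        coms = []
        masses = []
        sizes = []
        for d in range(1, n_dom + 1):
            mask = labels == d
            m = raw[mask]
            total = m.sum()
            ys, xs = np.nonzero(mask)
            if total > 0:
                com = np.array([np.sum(ys * m) / total, np.sum(xs * m) / total])
            else:  # smoothed-only domain: geometric centre
                com = np.array([ys.mean(), xs.mean()])
            coms.append(com)
            masses.append(total)
            sizes.append(int(mask.sum()))

        # same-bin grouping: domains closer than the merge radius share an ID
        group = list(range(n_dom))
        for a in range(n_dom):
            for b in range(a + 1, n_dom):
                if np.linalg.norm(coms[a] - coms[b]) < merge_px:
                    gb = group[b]
                    ga = group[a]
                    for c in range(n_dom):
                        if group[c] == gb:
                            group[c] = ga

        # aggregate grouped domains: one COM per wave per bin
        agg: dict[int, list[int]] = {}
        for d, g in enumerate(group):
            agg.setdefault(g, []).append(d)
        bin_waves = {}
        for g, members in agg.items():
            mass = sum(masses[d] for d in members)
            size = sum(sizes[d] for d in members)
            if mass > 0:
                com = sum(coms[d] * masses[d] for d in members) / mass
            else:
                com = sum(coms[d] for d in members) / len(members)
            bin_waves[g] = (com, size)

        # ID propagation from the previous bin
        assigned = {}
        for g, (com, size) in bin_waves.items():
            best_id, best_dist = None, merge_px
            for wid, pcom in prev.items():
                dist = np.linalg.norm(com - pcom)
                if dist < best_dist:
                    best_id, best_dist = wid, dist
            if best_id is None:
                best_id = next_id
                next_id += 1
            if best_id in assigned:  # two groups inherit one ID: union COM
                pc, ps = assigned[best_id]
                assigned[best_id] = ((pc * ps + com * size) / (ps + size), ps + size)
            else:
                assigned[best_id] = (com, size)

        prev = {}
        for wid, (com, size) in assigned.items():
            prev[wid] = com
            rec = tracks.setdefault(wid, {"t": [], "com": [], "bins": 0})
            rec["t"].append(t)
            rec["com"].append(com)
            rec["bins"] += size

    out: list[WaveTrack] = []
    for wid, rec in sorted(tracks.items()):
        ts = np.asarray(rec["t"])
        com = np.asarray(rec["com"])  # pixel units, (n, 2) as (y, x)
        n = len(ts)
        if n < 5:
            continue
        # zero-pad, smooth in time (SD = com_smooth_sigma), drop 2 from each end
        pad = 4
        padded = np.zeros((n + 2 * pad, 2))
        padded[pad : pad + n] = com
        sm = ndimage.gaussian_filter1d(
            padded, sigma=com_smooth_sigma / bin_s, axis=0, mode="constant"
        )[pad : pad + n]
        traj = sm[2:-2]
        kept_t = ts[2:-2]
        if len(traj) < 2:
            continue
        duration = (len(traj) - 1) * bin_s
        if duration <= min_duration - bin_s * 0.5:
            continue
        if rec["bins"] < min_spacetime_bins:
            continue
        mean_com = traj.mean(axis=0)
        if not (
            edge_margin <= mean_com[0] <= ny - 1 - edge_margin
            and edge_margin <= mean_com[1] <= nx - 1 - edge_margin
        ):
            continue
        steps = np.linalg.norm(np.diff(traj, axis=0), axis=1) * spacing
        path = float(steps.sum())
        out.append(
            WaveTrack(
                wave_id=wid,
                t=kept_t * bin_s,
                com=traj * spacing,
                n_spacetime_bins=rec["bins"],
                path_length=path,
                duration=duration,
                speed=path / duration,
                mean_com=mean_com * spacing,
            )
        )
    return out


def angle_to_distance(A_deg: float, r_eye: float) -> float:
    """Visual angle (degrees) to retinal distance (mm): R = pi * r * A / 135."""
    if r_eye <= 0:
        raise ValueError("eye radius must be positive")
    return np.pi * r_eye * A_deg / 135.0


def distance_to_angle(R_mm: float, r_eye: float) -> float:
    """Retinal distance (mm) to visual angle (degrees): A = 135 R / (pi r)."""
    if r_eye <= 0:
        raise ValueError("eye radius must be positive")
    return 135.0 * R_mm / (np.pi * r_eye)
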