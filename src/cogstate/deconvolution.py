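"""Sparse deconvolution of skin conductance into sudomotor impulses.

The phasic (fast) component of a skin-conductance trace is modeled as a
sparse train of autonomic nervous system impulses convolved with a
stereotyped bi-exponential response kernel, riding on a slowly varying
tonic baseline.  Recovery is by nonnegative l1-penalised least squares,
minimised by cyclic coordinate descent:

    minimise_{u >= 0}  0.5 * ||y - tonic - H u||^2 + sparsity * ||u||_1

where H is the (truncated Toeplitz) convolution matrix of the kernel.  The
tonic baseline is a cubic spline through running minima, which is
deterministic and cheap; tonic-level (SCL) analysis is out of scope here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator


@dataclass(frozen=True)
class PhasicKernel:
    """Bi-exponential skin-conductance response kernel.

    h(t) = c (e^{-t/tau_decay} - e^{-t/tau_rise}) for t >= 0, zero before,
    with c chosen so the peak equals one.  Defaults are typical literature
    values for the stereotyped SCR shape.
    """

    tau_rise: float = 0.7
    tau_decay: float = 3.0

    def __post_init__(self):
        if not (0.0 < self.tau_rise < self.tau_decay):
            raise ValueError(
                f"need 0 < tau_rise < tau_decay, got {self.tau_rise}, {self.tau_decay}"
            )

    @property
    def peak_time(self) -> float:
        """Analytic maximiser of the bi-exponential."""
        return math.log(self.tau_decay / self.tau_rise) / (
            1.0 / self.tau_rise - 1.0 / self.tau_decay
        )

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tp = self.peak_time
        c = 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))
        h = c * (np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise))
        return np.where(t >= 0, h, 0.0)


def build_kernel(tau_rise: float, tau_decay: float, fs: float,
                 duration: float) -> np.ndarray:
    """Discretise a unit-peak bi-exponential kernel at sampling rate fs.

    Returns round(duration * fs) samples starting at t = 0 (so h[0] = 0).
    A duration shorter than the decay constant is allowed but truncates the
    tail; a warning is emitted.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    kernel = PhasicKernel(tau_rise, tau_decay)
    if duration < tau_decay:
        warnings.warn(
            f"kernel duration {duration}s < tau_decay {tau_decay}s: truncated tail",
            stacklevel=2,
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return kernel.evaluate(t)


@dataclass
class SCRecording:
    """A raw skin-conductance trace in microsiemens."""

    samples: np.ndarray
    fs: float
    t_start: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 2:
            raise ValueError("recording needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class ImpulseTrain:
    """Sparse sudomotor impulses: event times plus positive amplitudes.

    ``tonic`` is the slowly-varying baseline on the recording grid (an
    array), or a scalar for synthetic trains that never saw a recording.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    tonic: np.ndarray | float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must align")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("impulse times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("impulse amplitudes must be positive")

    def __len__(self) -> int:
        return self.times.size

    @property
    def tonic_level(self) -> float:
        return float(np.mean(self.tonic))


def tonic_baseline(samples: np.ndarray, fs: float,
                   knot_spacing: float = 10.0, stat: str = "min") -> np.ndarray:
    """Slow baseline as a cubic spline through running minima.

    The trace is cut into windows of ``knot_spacing`` seconds; each window
    contributes one knot (its minimum, placed at the window centre).  With
    ``stat="min"`` the knots are debiased by the expected minimum of
    Gaussian sensor noise over the window (noise sd estimated from first
    differences); ``stat="median"`` takes the window median instead, the
    right summary once the phasic component has been subtracted.  With
    fewer than four knots the spline degenerates to linear interpolation.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    win = max(int(round(knot_spacing * fs)), 1)
    if stat == "min":
        # robust noise sd from first differences (phasic part is smooth)
        noise_sd = float(np.median(np.abs(np.diff(samples)))) / (0.6745 * math.sqrt(2))
        debias = noise_sd * math.sqrt(2.0 * math.log(max(win, 2)))
        summary = lambda seg: seg.min() + debias
    elif stat == "median":
        summary = lambda seg: float(np.median(seg))
    else:
        raise ValueError(f"unknown stat '{stat}'")
    knots_t, knots_v = [], []
    for start in range(0, n, win):
        seg = samples[start:start + win]
        knots_t.append(start + len(seg) / 2.0)
        knots_v.append(summary(seg))
    # anchor both edges so the spline never extrapolates
    knots_t = [0.0] + knots_t + [float(n - 1)]
    knots_v = [knots_v[0]] + knots_v + [knots_v[-1]]
    knots_t, idx = np.unique(knots_t, return_index=True)
    knots_v = np.asarray(knots_v)[idx]
    t = np.arange(n, dtype=float)
    if len(knots_t) < 4:
        return np.interp(t, knots_t, knots_v)
    # shape-preserving cubic: no overshoot between knots
    spline = PchipInterpolator(knots_t, knots_v)
    return spline(t)


def _coordinate_descent(y: np.ndarray, h: np.ndarray, sparsity: float,
                        max_iters: int, tol: float) -> np.ndarray:
    """Cyclic coordinate descent for min_u>=0 0.5||y - Hu||^2 + s||u||_1.

    The objective is convex, so it must not increase between sweeps
    (asserted); convergence when the largest coordinate move in a sweep
    drops below ``tol``.
    """
    n, L = y.size, h.size
    # squared norm of the (possibly boundary-truncated) kernel per coordinate
    h_cum = np.cumsum(h ** 2)
    tail = np.minimum(L, n - np.arange(n))
    norms = np.full(n, h_cum[-1])
    short = tail < L
    norms[short] = h_cum[tail[short] - 1]
    norms = np.maximum(norms, 1e-30)

    u = np.zeros(n)
    resid = y.copy()

    def objective() -> float:
        return 0.5 * float(resid @ resid) + sparsity * float(u.sum())

    prev_obj = objective()
    for _ in range(max_iters):
        max_delta = 0.0
        for i in range(n):
            li = int(tail[i])
            hi = h[:li]
            g = u[i] * norms[i] + hi @ resid[i:i + li]
            new = max(0.0, (g - sparsity) / norms[i])
            d = new - u[i]
            if d != 0.0:
                resid[i:i + li] -= d * hi
                u[i] = new
                max_delta = max(max_delta, abs(d))
        obj = objective()
        if obj > prev_obj + 1e-9 * (1.0 + abs(prev_obj)):
            raise RuntimeError("coordinate descent objective increased")
        prev_obj = obj
        if max_delta < tol:
            break
    return u


def deconvolve(scr: SCRecording, kernel: PhasicKernel | None = None,
               sparsity: float = 0.05, max_iters: int = 200,
               tol: float = 1e-8, knot_spacing: float = 10.0,
               amplitude_floor: float = 0.01,
               kernel_duration: float | None = None) -> ImpulseTrain:
    """Recover a sparse impulse train from a skin-conductance trace.

    Coordinate descent on the nonnegative-lasso objective; the objective is
    convex, so each full sweep can only decrease it (asserted).  After
    convergence, amplitudes below ``amplitude_floor`` times the maximum are
    dropped and runs of adjacent nonzero samples are merged by amplitude
    sum (downstream binning is per-bin anyway).
    """
    if sparsity < 0:
        raise ValueError(f"sparsity penalty must be >= 0, got {sparsity}")
    kernel = kernel or PhasicKernel()
    y_raw = scr.samples
    if np.ptp(y_raw) == 0.0:
        return ImpulseTrain(np.empty(0), np.empty(0),
                            tonic=np.full_like(y_raw, y_raw.mean()))

    dur = kernel_duration or min(8.0 * kernel.tau_decay, scr.duration)
    h = build_kernel(kernel.tau_rise, kernel.tau_decay, scr.fs, dur)

    # alternating baseline/impulse refinement: the initial running-minimum
    # tonic absorbs slow SCR tails, so re-estimate it on the
    # phasic-subtracted residual (window medians) and re-fit
    tonic = tonic_baseline(y_raw, scr.fs, knot_spacing)
    u = _coordinate_descent(y_raw - tonic, h, sparsity, max_iters, tol)
    for _ in range(3):
        phasic = np.convolve(u, h)[:y_raw.size]
        tonic = tonic_baseline(y_raw - phasic, scr.fs, knot_spacing,
                               stat="median")
        u = _coordinate_descent(y_raw - tonic, h, sparsity, max_iters, tol)

    if u.max(initial=0.0) > 0.0:
        u[u < amplitude_floor * u.max()] = 0.0
    idx = np.flatnonzero(u)
    if idx.size == 0:
        return ImpulseTrain(np.empty(0), np.empty(0), tonic=tonic)

    # merge runs of adjacent samples: sum amplitudes, keep the peak position
    times, amps = [], []
    run = [idx[0]]
    for j in idx[1:]:
        if j == run[-1] + 1:
            run.append(j)
        else:
            times.append(run[int(np.argmax(u[run]))])
            amps.append(u[run].sum())
            run = [j]
    times.append(run[int(np.argmax(u[run]))])
    amps.append(u[run].sum())

    return ImpulseTrain(scr.t_start + np.asarray(times) / scr.fs,
                        np.asarray(amps), tonic=tonic)


def reconstruct_and_score(impulses: ImpulseTrain, kernel: PhasicKernel,
                          scr: SCRecording) -> tuple[np.ndarray, float]:
    """Rebuild tonic + sum of kernel responses and score it with R^2."""
    n = scr.samples.size
    phasic = np.zeros(n)
    dur = min(8.0 * kernel.tau_decay, scr.duration)
    h = build_kernel(kernel.tau_rise, kernel.tau_decay, scr.fs, dur)
    for t, a in zip(impulses.times, impulses.amplitudes):
        i = int(round((t - scr.t_start) * scr.fs))
        if 0 <= i < n:
            li = min(h.size, n - i)
            phasic[i:i + li] += a * h[:li]
    tonic = impulses.tonic
    recon = (tonic if np.ndim(tonic) else np.full(n, float(tonic))) + phasic
    ss_res = float(np.sum((scr.samples - recon) ** 2))
    ss_tot = float(np.sum((scr.samples - scr.samples.mean()) ** 2))
    if ss_tot <= 1e-300:
        r2 = 1.0 if ss_res <= 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return recon, r2
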