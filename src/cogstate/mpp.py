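"""Marked-point-process decoder for the hidden arousal state.

The arousal state x_j follows a random walk.  In each time bin an
autonomic impulse occurs with probability a_j = sigmoid(x_j + beta), and an
occurring impulse carries a Gaussian mark (its amplitude)
r_j ~ N(gamma0 + gamma1 x_j, sigma_v^2).  The filter is a Laplace-style
posterior-mode update (the one-step posterior combines a Gaussian prior
with a Bernoulli and, on event bins, a Gaussian mark likelihood), followed
by a standard fixed-interval smoother.  An EM loop estimates the mark
regression, the mark noise, and the process noise; the Bernoulli offset
beta is held fixed at the logit of the empirical event rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._util import (VARIANCE_FLOOR, logit, sigmoid,
                    solve_decreasing_score)
from .deconvolution import ImpulseTrain
from .trajectory import StateTrajectory


@dataclass
class MPPSeries:
    """Binned marked point process: event indicators plus mark amplitudes.

    ``r[j]`` is the mean impulse amplitude in bin j and is NaN wherever
    ``n[j] == 0``.
    """

    n: np.ndarray
    r: np.ndarray
    bin_width: float

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        if self.bin_width <= 0:
            raise ValueError(f"bin width must be positive, got {self.bin_width}")
        if self.n.shape != self.r.shape:
            raise ValueError("n and r must align")
        if np.any((self.n != 0) & (self.n != 1)):
            raise ValueError("event indicators must be 0/1")
        ev = self.n == 1
        if not np.all(np.isfinite(self.r[ev])):
            raise ValueError("marks on event bins must be finite")
        if np.any(np.isfinite(self.r[~ev])):
            raise ValueError("marks defined on non-event bins")

    def __len__(self) -> int:
        return self.n.size

    @property
    def event_rate(self) -> float:
        return float(self.n.mean())


@dataclass(frozen=True)
class MPPArousalParams:
    """Parameters of the marked-point-process arousal model.

    a0 is the mean event probability; the Bernoulli offset is
    beta = logit(a0).  gamma0/gamma1 are the mark-regression intercept and
    slope, sigma_v_sq the mark noise, sigma_eps_sq the random-walk process
    noise.
    """

    sigma_eps_sq: float = 0.05
    a0: float = 0.3
    gamma0: float = 0.5
    gamma1: float = 0.5
    sigma_v_sq: float = 0.1

    def __post_init__(self):
        if self.sigma_eps_sq <= 0 or self.sigma_v_sq <= 0:
            raise ValueError("variances must be positive")
        if not 0.0 < self.a0 < 1.0:
            raise ValueError(f"a0 must lie in (0, 1), got {self.a0}")

    @property
    def beta(self) -> float:
        return logit(self.a0)


def bin_to_mpp(impulses: ImpulseTrain, bin_width: float, span: float,
               t_start: float = 0.0) -> MPPSeries:
    """Aggregate an impulse train onto half-open bins [t, t + width).

    A bin with at least one impulse is an event; its mark is the mean
    amplitude of the impulses it contains.  Impulses outside the span are
    dropped (with a warning giving the count).
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    n_bins = int(math.ceil(span / bin_width))
    n = np.zeros(n_bins, dtype=int)
    r_sum = np.zeros(n_bins)
    r_cnt = np.zeros(n_bins, dtype=int)
    rejected = 0
    for t, a in zip(impulses.times, impulses.amplitudes):
        j = int(math.floor((t - t_start) / bin_width))
        if 0 <= j < n_bins:
            n[j] = 1
            r_sum[j] += a
            r_cnt[j] += 1
        else:
            rejected += 1
    if rejected:
        warnings.warn(f"{rejected} impulses outside the binning span dropped",
                      stacklevel=2)
    r = np.full(n_bins, np.nan)
    ev = n == 1
    r[ev] = r_sum[ev] / r_cnt[ev]
    return MPPSeries(n, r, bin_width)


def _mode_update(n_k: int, r_k: float, x_pred: float, var_pred: float,
                 beta: float, g0: float, g1: float, sv2: float,
                 index: int | None = None) -> tuple[float, float, float]:
    """Single posterior-mode update; returns (x, var, event probability)."""

    def score(x: float) -> float:
        s = (x_pred - x) / var_pred + (n_k - sigmoid(x + beta))
        if n_k:
            s += g1 * (r_k - g0 - g1 * x) / sv2
        return s

    x = solve_decreasing_score(score, x_pred, math.sqrt(var_pred), index)
    a = float(sigmoid(x + beta))
    info = 1.0 / var_pred + a * (1.0 - a) + (n_k * g1 * g1 / sv2)
    var = 1.0 / info
    if var <= 0:
        raise RuntimeError(f"negative posterior variance at bin {index}")
    return x, var, a


def _rts_smooth(x_filt, var_filt, x_pred, var_pred, rho: float = 1.0):
    """Fixed-interval (RTS) smoother for a scalar AR(1)/random-walk state.

    Gain A_k = rho * var_filt[k] / var_pred[k+1]; also returns the lag-one
    smoothed cross-moment E[x_{k+1} x_k] = x_{k+1|K} x_{k|K} + A_k s2_{k+1|K}.
    """
    k = len(x_filt)
    x_s = x_filt.copy()
    v_s = var_filt.copy()
    gain = np.zeros(max(k - 1, 0))
    cross = np.zeros(max(k - 1, 0))
    for j in range(k - 2, -1, -1):
        a = rho * var_filt[j] / var_pred[j + 1]
        x_s[j] = x_filt[j] + a * (x_s[j + 1] - x_pred[j + 1])
        v_s[j] = max(var_filt[j] + a * a * (v_s[j + 1] - var_pred[j + 1]),
                     VARIANCE_FLOOR)
        gain[j] = a
        cross[j] = x_s[j + 1] * x_s[j] + a * v_s[j + 1]
    return x_s, v_s, gain, cross


def mpp_decode(obs: MPPSeries, params: MPPArousalParams, x0: float = 0.0,
               var0: float | None = None) -> StateTrajectory:
    """Filter + smooth the arousal state from binned events and marks."""
    if var0 is None:
        var0 = params.sigma_eps_sq
    if var0 <= 0 or not np.isfinite(x0):
        raise ValueError("x0 must be finite and var0 positive")
    k = len(obs)
    beta = params.beta
    x_pred = np.zeros(k)
    var_pred = np.zeros(k)
    x_filt = np.zeros(k)
    var_filt = np.zeros(k)
    xp, vp = x0, var0
    for j in range(k):
        x_pred[j], var_pred[j] = xp, vp
        x_filt[j], var_filt[j], _ = _mode_update(
            int(obs.n[j]), float(obs.r[j]) if obs.n[j] else 0.0,
            xp, vp, beta, params.gamma0, params.gamma1, params.sigma_v_sq,
            index=j)
        xp = x_filt[j]
        vp = var_filt[j] + params.sigma_eps_sq
    x_s, v_s, gain, cross = _rts_smooth(x_filt, var_filt, x_pred, var_pred)
    prob = sigmoid(x_s + beta)
    return StateTrajectory(x_pred, var_pred, x_filt, var_filt, x_s, v_s,
                           prob, gain, cross)


def _mark_regression(x, ex2, r, mask):
    """Expected-value linear regression of marks on the state over event bins."""
    xs, e2, rs = x[mask], ex2[mask], r[mask]
    m = xs.size
    sx, sxx = xs.sum(), e2.sum()
    sr, srx = rs.sum(), (rs * xs).sum()
    det = m * sxx - sx * sx
    if abs(det) < 1e-12:
        g1 = 0.0
        g0 = sr / m
    else:
        g1 = (m * srx - sx * sr) / det
        g0 = (sr - g1 * sx) / m
    resid = np.mean(rs ** 2 - 2 * g0 * rs - 2 * g1 * rs * xs
                    + g0 ** 2 + 2 * g0 * g1 * xs + g1 ** 2 * e2)
    return g0, g1, max(float(resid), VARIANCE_FLOOR)


def _mpp_loglik(obs: MPPSeries, params: MPPArousalParams,
                traj: StateTrajectory) -> float:
    """Laplace approximation of the marginal (observed-data) log-likelihood.

    One-step predictive decomposition evaluated at the filtered modes:
    log p(y_j | y_{<j}) ~ log lik(x*) - (x* - x_pred)^2 / (2 var_pred)
    + 0.5 log(var_filt / var_pred).
    """
    x = traj.x_filt
    a = sigmoid(x + params.beta)
    ll = float(np.sum(obs.n * np.log(a) + (1 - obs.n) * np.log(1 - a)))
    ev = obs.n == 1
    if ev.any():
        m = int(ev.sum())
        ll += float(np.sum(-(obs.r[ev] - params.gamma0
                             - params.gamma1 * x[ev]) ** 2
                           / (2 * params.sigma_v_sq))) \
            - 0.5 * m * math.log(2 * math.pi * params.sigma_v_sq)
    ll += float(np.sum(-(x - traj.x_pred) ** 2 / (2 * traj.var_pred)))
    ll += 0.5 * float(np.sum(np.log(traj.var_filt / traj.var_pred)))
    return ll


def mpp_em(obs: MPPSeries, init: MPPArousalParams | None = None,
           max_iters: int = 50, tol: float = 1e-4
           ) -> tuple[MPPArousalParams, StateTrajectory, list[float]]:
    """EM for the MPP arousal model.

    E-step: posterior-mode filter + smoother (Laplace-Gaussian posterior).
    The returned trace is the Laplace-approximate marginal log-likelihood.
    M-step: closed forms — mark regression from smoothed moments, mark
    noise from expected residuals, process noise from expected squared
    increments.  beta stays fixed at logit(mean event rate).
    """
    if obs.n.sum() == 0:
        raise ValueError("mark model unidentifiable: no event bins observed")
    a0 = min(max(obs.event_rate, 1.0 / (2 * len(obs))),
             1.0 - 1.0 / (2 * len(obs)))
    if init is None:
        ev = obs.n == 1
        init = MPPArousalParams(sigma_eps_sq=0.05, a0=a0,
                                gamma0=float(np.mean(obs.r[ev])), gamma1=0.1,
                                sigma_v_sq=max(float(np.var(obs.r[ev])),
                                               VARIANCE_FLOOR * 10))
    else:
        init = replace(init, a0=a0)

    params = init
    traj = mpp_decode(obs, params)
    trace: list[float] = [_mpp_loglik(obs, params, traj)]
    for _ in range(max_iters):
        x, ex2 = traj.x_smooth, traj.ex2
        g0, g1, sv2 = _mark_regression(x, ex2, obs.r, obs.n == 1)
        inc = ex2[1:] + ex2[:-1] - 2 * traj.cross_cov
        se2 = max(float(inc.mean()), VARIANCE_FLOOR)
        new = MPPArousalParams(sigma_eps_sq=se2, a0=params.a0,
                               gamma0=g0, gamma1=g1, sigma_v_sq=sv2)
        change = max(
            abs(getattr(new, f) - getattr(params, f))
            / (1.0 + abs(getattr(params, f)))
            for f in ("sigma_eps_sq", "gamma0", "gamma1", "sigma_v_sq"))
        if change < tol:
            break
        new_traj = mpp_decode(obs, new)
        ll = _mpp_loglik(obs, new, new_traj)
        if ll < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
            # the approximate E-step's fixed point sits slightly past the
            # likelihood peak; keep the best iterate
            break
        params, traj = new, new_traj
        trace.append(ll)
    else:
        warnings.warn("EM iteration cap reached; returning best-so-far",
                      stacklevel=2)
    return params, traj, trace
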