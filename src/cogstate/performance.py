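"""Decoder for the hidden cognitive-performance state during an n-back task.

The performance state z_k follows an AR(1) process
z_k = rho z_{k-1} + w_k.  Each trial yields a binary correctness
m_k ~ Bernoulli(sigmoid(z_k + mu)) and a log reaction time
log(tau_k) = alpha0 + alpha1 z_k + delta_k.  Under the convention that
higher performance means faster responses, alpha1 is expected negative
(it is initialised at -0.1 but not constrained).

Trials with no response are coded m_k = 0 with missing reaction time; the
update then uses only the Bernoulli term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import (VARIANCE_FLOOR, logit, sigmoid,
                    solve_decreasing_score)
from .mpp import _rts_smooth
from .trajectory import StateTrajectory

TRIAL_COLUMNS = ["trial", "session", "task", "correct", "rt_s"]


@dataclass(frozen=True)
class PerfParams:
    """Parameters of the AR(1) performance model.

    p0 is the mean probability of a correct response; the Bernoulli offset
    is mu = logit(p0).  alpha0/alpha1 map the state to log reaction time.
    """

    rho: float = 0.99
    sigma_w_sq: float = 0.01
    p0: float = 0.8
    alpha0: float = 0.0
    alpha1: float = -0.3
    sigma_delta_sq: float = 0.04

    def __post_init__(self):
        if abs(self.rho) > 1.0:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")
        if self.sigma_w_sq <= 0 or self.sigma_delta_sq <= 0:
            raise ValueError("variances must be positive")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")

    @property
    def mu(self) -> float:
        return logit(self.p0)

    def stationary_var(self) -> float:
        if abs(self.rho) < 1.0:
            return self.sigma_w_sq / (1.0 - self.rho ** 2)
        return self.sigma_w_sq


def trials_to_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract (m, l) = (correctness, log reaction time) from a trial table.

    Reaction times must be positive where present; missing reaction times
    (no response) become NaN in l.
    """
    for col in ("correct", "rt_s"):
        if col not in trials.columns:
            raise ValueError(f"trial table missing column '{col}'")
    m = trials["correct"].to_numpy(dtype=float)
    if np.any((m != 0) & (m != 1)):
        raise ValueError("correct must be 0/1")
    tau = trials["rt_s"].to_numpy(dtype=float)
    if np.any(tau[np.isfinite(tau)] <= 0):
        raise ValueError("reaction times must be positive")
    l = np.where(np.isfinite(tau), np.log(np.where(np.isfinite(tau), tau, 1.0)),
                 np.nan)
    return m.astype(int), l


def perf_decode(trials: pd.DataFrame | tuple[np.ndarray, np.ndarray],
                params: PerfParams, z0: float = 0.0,
                var0: float | None = None) -> StateTrajectory:
    """Filter + smooth the performance state from correctness and log-RT."""
    if isinstance(trials, pd.DataFrame):
        m, l = trials_to_arrays(trials)
    else:
        m, l = np.asarray(trials[0], dtype=int), np.asarray(trials[1], dtype=float)
    if var0 is None:
        var0 = params.stationary_var()
    k = m.size
    mu, a0c, a1c, sd2 = params.mu, params.alpha0, params.alpha1, params.sigma_delta_sq
    x_pred = np.zeros(k)
    var_pred = np.zeros(k)
    x_filt = np.zeros(k)
    var_filt = np.zeros(k)
    zp, vp = params.rho * z0, params.rho ** 2 * var0 + params.sigma_w_sq
    for j in range(k):
        x_pred[j], var_pred[j] = zp, vp
        has_rt = np.isfinite(l[j])

        def score(z: float) -> float:
            s = (zp - z) / vp + (m[j] - sigmoid(z + mu))
            if has_rt:
                s += a1c * (l[j] - a0c - a1c * z) / sd2
            return s

        z = solve_decreasing_score(score, zp, math.sqrt(vp), index=j)
        p = float(sigmoid(z + mu))
        info = 1.0 / vp + p * (1.0 - p) + (a1c * a1c / sd2 if has_rt else 0.0)
        x_filt[j], var_filt[j] = z, 1.0 / info
        zp = params.rho * z
        vp = params.rho ** 2 * var_filt[j] + params.sigma_w_sq
    x_s, v_s, gain, cross = _rts_smooth(x_filt, var_filt, x_pred, var_pred,
                                        rho=params.rho)
    prob = sigmoid(x_s + mu)
    return StateTrajectory(x_pred, var_pred, x_filt, var_filt, x_s, v_s,
                           prob, gain, cross)


def _clipped_mean_rate(m: np.ndarray) -> float:
    k = m.size
    return float(min(max(m.mean(), 1.0 / (2 * k)), 1.0 - 1.0 / (2 * k)))


def _perf_loglik(m, l, params: PerfParams, traj: StateTrajectory) -> float:
    """Laplace approximation of the marginal (observed-data) log-likelihood,
    via the one-step predictive decomposition at the filtered modes."""
    x = traj.x_filt
    p = sigmoid(x + params.mu)
    ll = float(np.sum(m * np.log(p) + (1 - m) * np.log(1 - p)))
    ok = np.isfinite(l)
    if ok.any():
        ll += float(np.sum(-(l[ok] - params.alpha0
                             - params.alpha1 * x[ok]) ** 2
                           / (2 * params.sigma_delta_sq))) \
            - 0.5 * int(ok.sum()) * math.log(2 * math.pi
                                             * params.sigma_delta_sq)
    ll += float(np.sum(-(x - traj.x_pred) ** 2 / (2 * traj.var_pred)))
    ll += 0.5 * float(np.sum(np.log(traj.var_filt / traj.var_pred)))
    return ll


def perf_em(trials: pd.DataFrame | tuple[np.ndarray, np.ndarray],
            init: PerfParams | None = None, max_iters: int = 50,
            tol: float = 1e-4
            ) -> tuple[PerfParams, StateTrajectory, list[float]]:
    """EM for the performance model.

    M-step closed forms: (alpha0, alpha1) by expected-value regression of
    log-RT on the state; sigma_delta^2 from expected residuals; rho from
    the lag-one moment ratio (clamped to [-1, 1]); sigma_w^2 from expected
    AR(1) residuals.  mu stays fixed at logit(mean correctness), clipped
    away from 0/1 for degenerate all-correct or all-incorrect sequences.
    """
    if isinstance(trials, pd.DataFrame):
        m, l = trials_to_arrays(trials)
    else:
        m, l = np.asarray(trials[0], dtype=int), np.asarray(trials[1], dtype=float)
    if m.size < 10:
        raise ValueError("need at least 10 trials for EM")
    p0 = _clipped_mean_rate(m)
    if init is None:
        ok = np.isfinite(l)
        init = PerfParams(rho=0.99, sigma_w_sq=0.01, p0=p0,
                          alpha0=float(np.mean(l[ok])) if ok.any() else 0.0,
                          alpha1=-0.1,
                          sigma_delta_sq=max(float(np.var(l[ok])), 1e-4)
                          if ok.any() else 0.04)
    else:
        init = replace(init, p0=p0)

    params = init
    traj = perf_decode((m, l), params)
    trace: list[float] = [_perf_loglik(m, l, params, traj)]
    for _ in range(max_iters):
        x, ex2 = traj.x_smooth, traj.ex2
        ok = np.isfinite(l)
        # expected-value regression of log-RT on z over responded trials
        xs, e2, ls = x[ok], ex2[ok], l[ok]
        nn = xs.size
        det = nn * e2.sum() - xs.sum() ** 2
        if nn >= 2 and abs(det) > 1e-12:
            a1 = (nn * (ls * xs).sum() - xs.sum() * ls.sum()) / det
            a0 = (ls.sum() - a1 * xs.sum()) / nn
        else:
            a1, a0 = params.alpha1, params.alpha0
        res = np.mean(ls ** 2 - 2 * a0 * ls - 2 * a1 * ls * xs
                      + a0 ** 2 + 2 * a0 * a1 * xs + a1 ** 2 * e2) if nn else params.sigma_delta_sq
        sd2 = max(float(res), VARIANCE_FLOOR)
        rho = float(np.clip(traj.cross_cov.sum() / max(ex2[:-1].sum(), 1e-12),
                            -1.0, 1.0))
        inc = ex2[1:] - 2 * rho * traj.cross_cov + rho ** 2 * ex2[:-1]
        sw2 = max(float(inc.mean()), VARIANCE_FLOOR)
        new = PerfParams(rho=rho, sigma_w_sq=sw2, p0=params.p0,
                         alpha0=a0, alpha1=a1, sigma_delta_sq=sd2)
        change = max(
            abs(getattr(new, f) - getattr(params, f))
            / (1.0 + abs(getattr(params, f)))
            for f in ("rho", "sigma_w_sq", "alpha0", "alpha1",
                      "sigma_delta_sq"))
        if change < tol:
            break
        new_traj = perf_decode((m, l), new)
        ll = _perf_loglik(m, l, new, new_traj)
        if ll < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
            # approximate E-step fixed point sits past the likelihood peak
            break
        params, traj = new, new_traj
        trace.append(ll)
    else:
        warnings.warn("EM iteration cap reached; returning best-so-far",
                      stacklevel=2)
    return params, traj, trace
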