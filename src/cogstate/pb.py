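"""Performance-based arousal decoder.

The arousal state x_k (per n-back trial) follows a random walk and is
observed through three simultaneous channels:

* a Bernoulli arousal-event indicator n_k with
  P(n_k = 1) = phi_k = sigmoid(x_k + q0);
* on event trials, a Gaussian mark r_k ~ N(gamma0 + gamma1 x_k, sigma_zeta^2)
  (the mean deconvolved impulse amplitude within the trial);
* the continuous performance state z_k, linked through an inverted-U
  quadratic z_k = lambda1 x_k^2 + lambda0 + psi_k (lambda1 expected
  negative, not constrained).

Filtering uses a Laplace posterior-mode update: the one-step score is
nonlinear (and can even be multimodal because of the quadratic channel),
so the mode is found by bracketed root finding, taking the root nearest
the prediction.  The smoother is the standard fixed-interval recursion;
second and fourth posterior moments use the Gaussian closed forms, the
fourth moment via E[x^4] = (E[x^2])^2 + 4 m^2 s^2 + 2 s^4 — exact for a
Gaussian.  EM alternates this approximate E-step with closed-form
M-step regressions on the expected moments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._util import (VARIANCE_FLOOR, expected_softplus, logit, sigmoid,
                    solve_score_nearest)
from .trajectory import StateTrajectory


@dataclass
class PBObservations:
    """Per-trial observation triples (event indicator, mark, performance).

    ``r[k]`` is NaN on non-event trials.
    """

    n: np.ndarray
    r: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.n.shape == self.r.shape == self.z.shape):
            raise ValueError("n, r, z must align")
        if np.any((self.n != 0) & (self.n != 1)):
            raise ValueError("event indicators must be 0/1")
        ev = self.n == 1
        if not np.all(np.isfinite(self.r[ev])):
            raise ValueError("marks on event trials must be finite")
        if np.any(np.isfinite(self.r[~ev])):
            raise ValueError("marks defined on non-event trials")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("performance values must be finite")

    def __len__(self) -> int:
        return self.n.size


@dataclass(frozen=True)
class PBParams:
    """Parameters of the performance-based arousal model.

    phi0 is the mean event probability (q0 = logit(phi0) is the Bernoulli
    offset); lambda1/lambda0 the quadratic performance observation;
    gamma0/gamma1 the mark regression; sigma_u_sq the random-walk process
    noise.
    """

    sigma_u_sq: float = 0.05
    phi0: float = 0.3
    lambda1: float = -0.8
    lambda0: float = 1.0
    sigma_psi_sq: float = 0.2
    gamma0: float = 0.5
    gamma1: float = 0.5
    sigma_zeta_sq: float = 0.1

    def __post_init__(self):
        for name in ("sigma_u_sq", "sigma_psi_sq", "sigma_zeta_sq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.phi0 < 1.0:
            raise ValueError(f"phi0 must lie in (0, 1), got {self.phi0}")

    @property
    def q0(self) -> float:
        return logit(self.phi0)

    @classmethod
    def neutral_init(cls, obs: PBObservations) -> "PBParams":
        """Data-driven neutral starting point for EM."""
        ev = obs.n == 1
        k = len(obs)
        phi0 = min(max(obs.n.mean(), 1.0 / (2 * k)), 1.0 - 1.0 / (2 * k))
        return cls(
            sigma_u_sq=0.1,
            phi0=float(phi0),
            lambda1=-0.1,
            lambda0=float(np.mean(obs.z)),
            sigma_psi_sq=max(float(np.var(obs.z)), 1e-4),
            gamma0=float(np.mean(obs.r[ev])),
            gamma1=0.1,
            sigma_zeta_sq=max(float(np.var(obs.r[ev])), 1e-4),
        )


@dataclass
class PBPosterior(StateTrajectory):
    """State trajectory plus the higher posterior moments the M-step needs."""

    Ex2: np.ndarray = None
    Ex4: np.ndarray = None
    Exx: np.ndarray = None

    def __post_init__(self):
        super().__post_init__()
        self.Ex2 = np.asarray(self.Ex2, dtype=float)
        self.Ex4 = np.asarray(self.Ex4, dtype=float)
        self.Exx = np.asarray(self.Exx, dtype=float)
        if np.any(self.Ex2 < self.x_smooth ** 2 - 1e-9):
            raise ValueError("E[x^2] below (E[x])^2")
        if np.any(self.Ex4 < self.Ex2 ** 2 - 1e-9):
            raise ValueError("E[x^4] below (E[x^2])^2")


def build_pb_observations(impulses, perf_traj: StateTrajectory,
                          windows: np.ndarray) -> PBObservations:
    """Assemble per-trial observation triples from impulses and performance.

    ``windows`` is a (K, 2) array of trial [start, end) times; the k-th
    performance value is the smoothed state of ``perf_traj`` at trial k,
    which must therefore have one entry per trial.  A trial is an event
    trial iff at least one impulse falls inside its window; its mark is
    the mean amplitude of those impulses.
    """
    windows = np.asarray(windows, dtype=float)
    k = windows.shape[0]
    if len(perf_traj) != k:
        raise ValueError(
            f"performance trajectory has {len(perf_traj)} entries "
            f"but the schedule has {k} trials")
    n = np.zeros(k, dtype=int)
    r = np.full(k, np.nan)
    for i, (start, end) in enumerate(windows):
        inside = (impulses.times >= start) & (impulses.times < end)
        if inside.any():
            n[i] = 1
            r[i] = float(impulses.amplitudes[inside].mean())
    return PBObservations(n, r, perf_traj.x_smooth.copy())


def gaussian_fourth_moment(mean, var):
    """E[x^4] for x ~ N(mean, var) via the second-order Taylor form.

    (E[x^2])^2 + 4 mean^2 var + 2 var^2, which coincides with the exact
    Gaussian moment mean^4 + 6 mean^2 var + 3 var^2.
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    ex2 = mean ** 2 + var
    return ex2 ** 2 + 4.0 * mean ** 2 * var + 2.0 * var ** 2


def pb_filter_step(n_k: int, r_k: float, z_k: float, x_pred: float,
                   var_pred: float, params: PBParams,
                   index: int | None = None) -> tuple[float, float, float]:
    """One posterior-mode update; returns (x, var, phi) at the mode.

    The score combines the Gaussian prior pull, the Bernoulli event term,
    the quadratic performance term, and (on event trials) the mark term.
    The observed-information bracket can turn non-positive where the
    Laplace approximation breaks down; the prediction variance is then
    kept as a conservative fallback.
    """
    if var_pred <= 0:
        raise ValueError("prediction variance must be positive")
    q0 = params.q0
    l1, l0, sp2 = params.lambda1, params.lambda0, params.sigma_psi_sq
    g0, g1, sz2 = params.gamma0, params.gamma1, params.sigma_zeta_sq

    def score(x: float) -> float:
        s = (x_pred - x) / var_pred + (n_k - sigmoid(x + q0))
        s += 2.0 * l1 * x * (z_k - l0 - l1 * x * x) / sp2
        if n_k:
            s += g1 * (r_k - g0 - g1 * x) / sz2
        return s

    x, _n_roots = solve_score_nearest(score, x_pred, math.sqrt(var_pred),
                                      index=index)
    phi = float(sigmoid(x + q0))
    bracket = (1.0 / var_pred + phi * (1.0 - phi)
               - (2.0 * l1 * (z_k - l0 - l1 * x * x)
                  - (2.0 * l1 * x) ** 2) / sp2)
    if n_k:
        bracket += g1 * g1 / sz2
    var = 1.0 / bracket if bracket > 0 else var_pred
    return x, max(var, VARIANCE_FLOOR), phi


def pb_filter(obs: PBObservations, params: PBParams, x0: float = 0.0,
              var0: float | None = None) -> StateTrajectory:
    """Forward posterior-mode filter over all trials."""
    if var0 is None:
        var0 = params.sigma_u_sq
    k = len(obs)
    x_pred = np.zeros(k)
    var_pred = np.zeros(k)
    x_filt = np.zeros(k)
    var_filt = np.zeros(k)
    phi = np.zeros(k)
    xp, vp = x0, var0
    for j in range(k):
        x_pred[j], var_pred[j] = xp, vp
        x_filt[j], var_filt[j], phi[j] = pb_filter_step(
            int(obs.n[j]), float(obs.r[j]) if obs.n[j] else 0.0,
            float(obs.z[j]), xp, vp, params, index=j)
        xp = x_filt[j]
        vp = var_filt[j] + params.sigma_u_sq
    # smoother fields are filled by pb_smooth; placeholders keep the
    # container valid for a forward-only result
    return StateTrajectory(x_pred, var_pred, x_filt, var_filt,
                           x_filt.copy(), var_filt.copy(), phi,
                           np.zeros(max(k - 1, 0)), np.zeros(max(k - 1, 0)))


def pb_smooth(traj: StateTrajectory, params: PBParams,
              moment_variance: str = "smoothed") -> PBPosterior:
    """Fixed-interval smoother plus the second/fourth posterior moments.

    ``moment_variance`` selects which variance enters the fourth-moment
    Taylor form: "smoothed" (consistent with the smoothed second moments
    used by the M-step, the default) or "filtered".
    """
    if moment_variance not in ("smoothed", "filtered"):
        raise ValueError(f"unknown moment_variance '{moment_variance}'")
    k = len(traj)
    x_s = traj.x_filt.copy()
    v_s = traj.var_filt.copy()
    gain = np.zeros(max(k - 1, 0))
    cross = np.zeros(max(k - 1, 0))
    for j in range(k - 2, -1, -1):
        a = traj.var_filt[j] / traj.var_pred[j + 1]
        x_s[j] = traj.x_filt[j] + a * (x_s[j + 1] - traj.x_pred[j + 1])
        v_s[j] = max(traj.var_filt[j] + a * a * (v_s[j + 1] - traj.var_pred[j + 1]),
                     VARIANCE_FLOOR)
        gain[j] = a
        cross[j] = x_s[j + 1] * x_s[j] + a * v_s[j + 1]
    ex2 = x_s ** 2 + v_s
    mv = v_s if moment_variance == "smoothed" else traj.var_filt
    ex4 = (x_s ** 2 + mv) ** 2 + 4.0 * x_s ** 2 * mv + 2.0 * mv ** 2
    if moment_variance == "filtered":
        # keep the Jensen ordering even when mixing variance definitions
        ex4 = np.maximum(ex4, ex2 ** 2)
    phi = sigmoid(x_s + params.q0)
    return PBPosterior(traj.x_pred, traj.var_pred, traj.x_filt,
                       traj.var_filt, x_s, v_s, phi, gain, cross,
                       Ex2=ex2, Ex4=ex4, Exx=cross.copy())


def pb_q3(obs: PBObservations, params: PBParams, post: PBPosterior) -> float:
    """Expected complete-data log-likelihood (Q3) of the model."""
    x, v = post.x_smooth, post.var_smooth
    ex2, ex4 = post.Ex2, post.Ex4
    q0 = params.q0
    q = float(np.sum(obs.n * (q0 + x) - expected_softplus(q0 + x, v)))
    ev = obs.n == 1
    m = int(ev.sum())
    if m:
        res2 = ((obs.r[ev] - params.gamma0 - params.gamma1 * x[ev]) ** 2
                + params.gamma1 ** 2 * v[ev])
        q += -0.5 * m * math.log(2 * math.pi * params.sigma_zeta_sq) \
             - float(res2.sum()) / (2 * params.sigma_zeta_sq)
    l0, l1 = params.lambda0, params.lambda1
    res2 = (obs.z ** 2 - 2 * l0 * obs.z - 2 * l1 * obs.z * ex2
            + l0 ** 2 + 2 * l0 * l1 * ex2 + l1 ** 2 * ex4)
    kk = len(obs)
    q += -0.5 * kk * math.log(2 * math.pi * params.sigma_psi_sq) \
         - float(res2.sum()) / (2 * params.sigma_psi_sq)
    inc = ex2[1:] + ex2[:-1] - 2 * post.Exx
    q += -0.5 * inc.size * math.log(2 * math.pi * params.sigma_u_sq) \
         - float(inc.sum()) / (2 * params.sigma_u_sq)
    return q


def _pb_mstep(obs: PBObservations, post: PBPosterior,
              params: PBParams) -> PBParams:
    x, ex2, ex4 = post.x_smooth, post.Ex2, post.Ex4
    k = len(obs)
    # mark regression over event trials
    ev = obs.n == 1
    xs, e2, rs = x[ev], ex2[ev], obs.r[ev]
    m = int(ev.sum())
    det = m * e2.sum() - xs.sum() ** 2
    if m >= 2 and abs(det) > 1e-12:
        g1 = (m * (rs * xs).sum() - xs.sum() * rs.sum()) / det
        g0 = (rs.sum() - g1 * xs.sum()) / m
    else:
        g0, g1 = float(rs.mean()), 0.0
    sz2 = max(float(np.mean(rs ** 2 - 2 * g0 * rs - 2 * g1 * rs * xs
                            + g0 ** 2 + 2 * g0 * g1 * xs + g1 ** 2 * e2)),
              VARIANCE_FLOOR)
    # quadratic performance regression: z on x^2 through (Ex2, Ex4)
    s2, s4 = ex2.sum(), ex4.sum()
    det = k * s4 - s2 ** 2
    if abs(det) > 1e-12:
        l1 = (k * (obs.z * ex2).sum() - s2 * obs.z.sum()) / det
        l0 = (obs.z.sum() - l1 * s2) / k
    else:
        l1, l0 = params.lambda1, params.lambda0
    sp2 = max(float(np.mean(obs.z ** 2 - 2 * l0 * obs.z - 2 * l1 * obs.z * ex2
                            + l0 ** 2 + 2 * l0 * l1 * ex2 + l1 ** 2 * ex4)),
              VARIANCE_FLOOR)
    # random-walk process noise from expected squared increments
    inc = ex2[1:] + ex2[:-1] - 2 * post.Exx
    su2 = max(float(inc.mean()), VARIANCE_FLOOR)
    return PBParams(sigma_u_sq=su2, phi0=params.phi0, lambda1=l1, lambda0=l0,
                    sigma_psi_sq=sp2, gamma0=g0, gamma1=g1,
                    sigma_zeta_sq=sz2)


def pb_grid_estep(obs: PBObservations, params: PBParams,
                  n_grid: int = 301, span: float | None = None,
                  x0: float = 0.0) -> tuple[PBPosterior, float]:
    """Exact E-step by discretizing the scalar state onto a grid.

    Forward-backward recursions over ``n_grid`` points give the posterior
    marginals, their exact second and fourth moments, the lag-one
    cross-moments, and the exact (up to discretization) marginal
    log-likelihood.  The default span is derived from the amplitude the
    quadratic performance channel implies, plus slack.
    """
    K = len(obs)
    p = params
    if span is None:
        amp = math.sqrt(max((p.lambda0 - float(np.min(obs.z)))
                            / max(abs(p.lambda1), 1e-6), 1.0))
        span = 1.5 * amp + 3.0
    xg = np.linspace(x0 - span, x0 + span, n_grid)
    T = np.exp(-(xg[None, :] - xg[:, None]) ** 2 / (2.0 * p.sigma_u_sq))
    T /= T.sum(axis=1, keepdims=True)
    phi_g = sigmoid(xg + p.q0)
    log_phi, log_1mphi = np.log(phi_g), np.log(1.0 - phi_g)

    lik = np.empty((K, n_grid))
    scales = np.empty(K)
    for k in range(K):
        l = log_phi if obs.n[k] else log_1mphi
        l = l - (obs.z[k] - p.lambda0 - p.lambda1 * xg ** 2) ** 2 \
            / (2 * p.sigma_psi_sq) - 0.5 * math.log(2 * math.pi * p.sigma_psi_sq)
        if obs.n[k]:
            l = l - (obs.r[k] - p.gamma0 - p.gamma1 * xg) ** 2 \
                / (2 * p.sigma_zeta_sq) \
                - 0.5 * math.log(2 * math.pi * p.sigma_zeta_sq)
        scales[k] = l.max()
        lik[k] = np.maximum(np.exp(l - scales[k]), 1e-300)

    alpha = np.empty((K, n_grid))
    c = np.empty(K)
    prior0 = np.exp(-(xg - x0) ** 2 / (2.0 * p.sigma_u_sq))
    prior0 /= prior0.sum()
    a = prior0 * lik[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for k in range(1, K):
        a = (alpha[k - 1] @ T) * lik[k]
        c[k] = a.sum()
        alpha[k] = a / c[k]
    ll = float(np.sum(np.log(c)) + np.sum(scales))

    beta = np.empty((K, n_grid))
    beta[-1] = 1.0
    for k in range(K - 2, -1, -1):
        b = T @ (lik[k + 1] * beta[k + 1])
        beta[k] = b / b.max()
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)

    ex = post @ xg
    ex2 = post @ xg ** 2
    ex4 = post @ xg ** 4
    var = np.maximum(ex2 - ex ** 2, VARIANCE_FLOOR)
    exx = np.empty(max(K - 1, 0))
    for k in range(K - 1):
        w = lik[k + 1] * beta[k + 1]
        v = T @ (w * xg)
        z_norm = float(alpha[k] @ (T @ w))
        exx[k] = float(alpha[k] @ (xg * v)) / z_norm

    xf = alpha @ xg
    vf = np.maximum(alpha @ xg ** 2 - xf ** 2, VARIANCE_FLOOR)
    x_pred = np.concatenate([[x0], xf[:-1]])
    var_pred = np.concatenate([[p.sigma_u_sq], vf[:-1] + p.sigma_u_sq])
    gain = vf[:-1] / var_pred[1:] if K > 1 else np.zeros(0)
    phi = sigmoid(ex + p.q0)
    return PBPosterior(x_pred, var_pred, xf, vf, ex, var, phi, gain,
                       exx.copy(), Ex2=ex2, Ex4=ex4, Exx=exx), ll


def _update_q0(obs: PBObservations, post: PBPosterior, q0: float) -> float:
    """Concave Newton update of the event-channel offset.

    Maximizes sum_k E[n_k (q0 + x_k) - log(1 + e^{q0 + x_k})] with a
    second-order correction for the posterior variance of x.
    """
    x, v = post.x_smooth, post.var_smooth
    for _ in range(50):
        s = sigmoid(q0 + x)
        grad = float(np.sum(obs.n - s - 0.5 * v * s * (1 - s) * (1 - 2 * s)))
        hess = -float(np.sum(s * (1 - s)))
        step = grad / hess
        q0 -= step
        if abs(step) < 1e-10:
            break
    return float(np.clip(q0, -8.0, 8.0))


def _event_calibration_slope(x: np.ndarray, n: np.ndarray) -> float:
    """Slope of a (lightly ridge-penalized) logistic fit of events on the
    decoded state.  Equals 1 when the event channel is self-consistent;
    a slope far from 1 flags a mis-scaled state estimate."""
    beta = np.array([0.0, 1.0])
    design = np.column_stack([np.ones_like(x), x])
    y = n.astype(float)
    for _ in range(60):
        p = sigmoid(design @ beta)
        grad = design.T @ (y - p) - 1e-4 * (beta - [0.0, 1.0])
        w = p * (1 - p)
        hess = -(design * w[:, None]).T @ design - 1e-4 * np.eye(2)
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.max(np.abs(step)) < 1e-9:
            break
    return float(np.clip(beta[1], 0.05, 20.0))


def _scale_matched_init(obs: PBObservations, lambda1: float) -> PBParams:
    """Moment-matched starting point at a prescribed quadratic gain.

    lambda0 from the upper envelope of z (the state crosses zero), the
    state's mean square from the z-channel at this lambda1, sigma_u^2 from
    random-walk geometry (mean square ~ K sigma_u^2 / 2), gamma1 from the
    mark spread at the implied state scale.
    """
    K = len(obs)
    phi0 = min(max(obs.n.mean(), 1.0 / (2 * K)), 1.0 - 1.0 / (2 * K))
    lam0 = float(np.quantile(obs.z, 0.99))
    mean_x2 = max(float(np.mean(lam0 - obs.z)) / abs(lambda1), 1e-3)
    ev = obs.n == 1
    g1 = max(float(np.std(obs.r[ev])) / math.sqrt(mean_x2), 0.01)
    return PBParams(
        sigma_u_sq=2.0 * mean_x2 / K, phi0=float(phi0), lambda1=lambda1,
        lambda0=lam0, sigma_psi_sq=max(float(np.var(obs.z)) * 0.1, 1e-3),
        gamma0=float(np.mean(obs.r[ev])), gamma1=g1,
        sigma_zeta_sq=max(float(np.var(obs.r[ev])) * 0.5, 1e-3))


_PARAM_NAMES = ("sigma_u_sq", "lambda1", "lambda0", "sigma_psi_sq",
                "gamma0", "gamma1", "sigma_zeta_sq")


def _em_run(obs: PBObservations, params: PBParams, max_iters: int,
            tol: float, e_step: str, estimate_q0: bool,
            moment_variance: str, x0: float, n_grid: int
            ) -> tuple[PBParams, PBPosterior, list[float], float]:
    """One EM run; returns (params, posterior, objective trace, final ll).

    With the grid E-step the trace is the exact marginal log-likelihood
    (non-decreasing by the EM guarantee, up to discretization); with the
    Laplace E-step it is the Q3 surrogate, which the approximate E-step
    can leave slightly non-monotone (warned, not fatal).
    """
    def estep(p):
        if e_step == "grid":
            return pb_grid_estep(obs, p, n_grid=n_grid, x0=x0)
        post = pb_smooth(pb_filter(obs, p, x0=x0), p, moment_variance)
        return post, pb_q3(obs, p, post)

    post, obj = estep(params)
    trace = [obj]
    for _ in range(max_iters):
        new = _pb_mstep(obs, post, params)
        if estimate_q0:
            new = replace(new, phi0=float(sigmoid(
                _update_q0(obs, post, params.q0))))
        change = max(abs(getattr(new, f) - getattr(params, f))
                     / (1.0 + abs(getattr(params, f)))
                     for f in _PARAM_NAMES)
        if change < tol:
            break
        params = new
        post, obj = estep(params)
        if e_step != "grid" and obj < trace[-1] - 1e-6 * (1 + abs(trace[-1])):
            warnings.warn(
                f"Q3 decreased ({trace[-1]:.6g} -> {obj:.6g}); the "
                "approximate E-step can cause small non-monotonicity",
                stacklevel=3)
        trace.append(obj)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-1]):
            break
    else:
        warnings.warn("EM iteration cap reached; returning best-so-far",
                      stacklevel=3)
    if e_step == "grid":
        ll = trace[-1]
    else:
        _, ll = pb_grid_estep(obs, params, n_grid=n_grid, x0=x0)
    return params, post, trace, ll


START_LAMBDA1 = (-0.3, -1.0, -3.0)


def pb_em(obs: PBObservations, init: PBParams | None = None,
          max_iters: int = 30, tol: float = 1e-4,
          e_step: str = "grid", estimate_q0: bool = True,
          moment_variance: str = "smoothed", x0: float = 0.0,
          n_grid: int = 301) -> tuple[PBParams, PBPosterior, list[float]]:
    """EM for the performance-based arousal model.

    The default E-step discretizes the scalar state onto a grid and runs
    exact forward-backward recursions; ``e_step="laplace"`` uses the
    per-trial posterior-mode filter plus moment closure instead.  The
    M-step is closed form: expected-value regressions of the marks on x
    (event trials) and of the performance on x^2 (through Ex2/Ex4), the
    process noise from expected squared increments, and — because the
    mark and performance channels are exactly invariant under rescaling
    the state, leaving the event channel as the only scale anchor — a
    Newton update of the event offset q0 (``estimate_q0=False`` pins it
    at logit(mean event rate) instead).

    When ``init`` is None the likelihood's weak identification of the
    state scale is handled by a small multi-start: moment-matched inits
    at quadratic gains lambda1 in (-0.3, -1, -3), selected by marginal
    log-likelihood with an event-calibration tie-break (among runs within
    5 nats, prefer the one whose logistic event-on-state slope is nearest
    1).  With an explicit ``init`` a single run is performed.
    """
    if len(obs) < 10:
        raise ValueError("need at least 10 trials")
    if obs.n.sum() == 0:
        raise ValueError("mark model unidentifiable: no event trials")
    if e_step not in ("grid", "laplace"):
        raise ValueError(f"unknown e_step '{e_step}'")

    if init is not None:
        k = len(obs)
        phi0 = min(max(obs.n.mean(), 1.0 / (2 * k)), 1.0 - 1.0 / (2 * k))
        start = init if estimate_q0 else replace(init, phi0=float(phi0))
        params, post, trace, _ = _em_run(obs, start, max_iters, tol, e_step,
                                         estimate_q0, moment_variance, x0,
                                         n_grid)
        return params, post, trace

    candidates = []
    for lam1 in START_LAMBDA1:
        params, post, trace, ll = _em_run(
            obs, _scale_matched_init(obs, lam1), max_iters, tol, e_step,
            estimate_q0, moment_variance, x0, n_grid)
        slope = _event_calibration_slope(post.x_smooth, obs.n)
        candidates.append((ll, abs(math.log(slope)), params, post, trace))
    best_ll = max(cand[0] for cand in candidates)
    near = [cand for cand in candidates if cand[0] > best_ll - 5.0]
    near.sort(key=lambda cand: cand[1])
    _, _, params, post, trace = near[0]
    return params, post, trace
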