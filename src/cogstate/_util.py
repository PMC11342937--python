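"""Shared numerical helpers for the state-space decoders."""

from __future__ import annotations

import math

import numpy as np

VARIANCE_FLOOR = 1e-8


class ConvergenceError(RuntimeError):
    """A root solve or iterative fit failed to converge."""


def sigmoid(x):
    """Numerically safe logistic function, scalar or array.

    Arguments are clipped to +/-36 so the result never rounds to exactly
    0 or 1 in double precision.
    """
    return 1.0 / (1.0 + np.exp(-np.clip(x, -36.0, 36.0)))


def logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def softplus(x):
    """log(1 + e^x) without overflow."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))


def expected_softplus(mean, var):
    """Second-order approximation of E[log(1 + e^s)] for s ~ N(mean, var).

    Used when evaluating expected complete-data log-likelihoods; the
    curvature correction is sigmoid'(mean) * var / 2.
    """
    s = sigmoid(mean)
    return softplus(mean) + 0.5 * var * s * (1.0 - s)


def solve_decreasing_score(score, x_pred: float, sd_pred: float,
                           index: int | None = None) -> float:
    """Root of a strictly decreasing score function.

    The posterior-mode equations of the linear-observation decoders have a
    strictly decreasing score in the state, hence a unique root.  Bracket at
    x_pred +/- 10 sd, widen by 10x if the bracket misses.
    """
    from scipy.optimize import brentq

    half = 10.0 * max(sd_pred, 1e-6)
    for _ in range(3):
        lo, hi = x_pred - half, x_pred + half
        if score(lo) > 0.0 > score(hi):
            return brentq(score, lo, hi, xtol=1e-12, rtol=1e-15,
                          maxiter=300)
        half *= 10.0
    where = "" if index is None else f" at index {index}"
    raise ConvergenceError(f"posterior-mode bracketing failed{where}")


def solve_score_nearest(score, x_pred: float, sd_pred: float,
                        index: int | None = None, n_grid: int = 41):
    """Root of a possibly non-monotone score; pick the root nearest x_pred.

    A quadratic observation can make the one-step posterior bimodal, i.e.
    the score can have several sign changes.  Scan a grid over
    x_pred +/- 10 sd, refine every sign-change interval by Brent's method,
    and return (root, n_roots).  If the grid shows no sign change, widen the
    bracket once by 10x before giving up.
    """
    from scipy.optimize import brentq

    half = 10.0 * max(sd_pred, 1e-6)
    for attempt in range(2):
        grid = np.linspace(x_pred - half, x_pred + half, n_grid)
        vals = np.array([score(g) for g in grid])
        signs = np.sign(vals)
        # exact zeros on the grid count as roots
        roots = [float(g) for g, v in zip(grid, vals) if v == 0.0]
        idx = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
        for i in idx:
            roots.append(brentq(score, grid[i], grid[i + 1],
                                xtol=1e-12, rtol=1e-15, maxiter=300))
        if roots:
            roots = np.asarray(roots)
            best = roots[np.argmin(np.abs(roots - x_pred))]
            return float(best), len(roots)
        half *= 10.0
        n_grid = 2 * n_grid - 1
    where = "" if index is None else f" at trial {index}"
    raise ConvergenceError(f"no sign change in posterior score{where}")


def coefficient_of_determination(truth, estimate) -> float:
    """R^2 of an estimated trajectory against its ground truth."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    ss_res = float(np.sum((truth - estimate) ** 2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot <= 1e-300:
        return 1.0 if ss_res <= 1e-12 else 0.0
    return 1.0 - ss_res / ss_tot
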