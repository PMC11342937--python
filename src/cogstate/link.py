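"""Arousal-performance link metrics.

Quantifies the Yerkes-Dodson (inverted-U) relation between decoded
arousal and performance: a robust quadratic regression of standardized
performance on standardized trial-averaged arousal, the point-biserial
correlation between task difficulty and arousal, and high-state indices
(posterior probability the latent state exceeds a threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectory import StateTrajectory

TUKEY_C = 4.685  # 95% Gaussian efficiency tuning constant


def standardize(values) -> np.ndarray:
    """Standard scores using the population standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = v.std()  # population sd
    if sd == 0.0:
        raise ValueError("cannot standardize a constant series")
    return (v - v.mean()) / sd


def trial_average_arousal(traj: StateTrajectory, windows: np.ndarray,
                          bin_width: float, t_start: float = 0.0) -> np.ndarray:
    """Mean smoothed arousal over the bins covering each trial window.

    A bin belongs to a trial when its centre falls inside the trial's
    half-open [start, end) window.  With bins aligned to trials this is
    the identity mapping.
    """
    windows = np.asarray(windows, dtype=float)
    centers = t_start + (np.arange(len(traj)) + 0.5) * bin_width
    out = np.empty(windows.shape[0])
    uncovered = []
    for i, (start, end) in enumerate(windows):
        inside = (centers >= start) & (centers < end)
        if not inside.any():
            uncovered.append(i)
            continue
        out[i] = traj.x_smooth[inside].mean()
    if uncovered:
        raise ValueError(f"trials not covered by any bin: {uncovered[:10]}"
                         + ("..." if len(uncovered) > 10 else ""))
    return out


@dataclass
class LinkFit:
    """Robust inverted-U fit Y = l1 X^2 + l2 X + l3 + e."""

    lambda1: float
    lambda2: float
    lambda3: float
    sigma_e_sq: float
    pvalues: np.ndarray        # per coefficient (l1, l2, l3)
    weights: np.ndarray        # final bisquare weights
    n_iter: int


def fit_inverted_u(x, y, c: float = TUKEY_C, max_iters: int = 100,
                   tol: float = 1e-8) -> LinkFit:
    """IRLS quadratic fit with Tukey bisquare weights.

    The scale is re-estimated each iteration as MAD/0.6745.  With clean
    (small-residual) data all weights stay 1 and the fit equals OLS.
    P-values come from t-statistics of the final weighted least-squares
    step with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points for the quadratic fit")
    design = np.column_stack([x ** 2, x, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design (constant or collinear X)")

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    w = np.ones(n)
    n_iter = 0
    for n_iter in range(1, max_iters + 1):
        resid = y - design @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad / 0.6745
        if scale < 1e-12:
            w = np.ones(n)
            break
        u = resid / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        wa = design * w[:, None]
        try:
            new = np.linalg.solve(wa.T @ design, wa.T @ y)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("weighted design became singular") from exc
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new

    resid = y - design @ beta
    dof = n - 3
    wrss = float(np.sum(w * resid ** 2))
    sigma2 = wrss / max(np.sum(w) - 3, 1.0)
    xtwx = design.T @ (design * w[:, None])
    cov = sigma2 * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return LinkFit(lambda1=float(beta[0]), lambda2=float(beta[1]),
                   lambda3=float(beta[2]),
                   sigma_e_sq=float(np.sum(resid ** 2) / max(dof, 1)),
                   pvalues=pvals, weights=w, n_iter=n_iter)


def point_biserial(dichotomous, continuous) -> float:
    """Point-biserial correlation between a 0/1 grouping and a continuous
    variable: (M1 - M0)/s_n * sqrt(n1 n0 / n^2) with the population sd.
    Equals the Pearson correlation with 0/1 coding.
    """
    g = np.asarray(dichotomous)
    v = np.asarray(continuous, dtype=float)
    if g.shape != v.shape:
        raise ValueError("group labels and values must align")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.size}")
    mask1 = g == levels[1]
    n1, n0 = int(mask1.sum()), int((~mask1).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be non-empty")
    sn = v.std()
    if sn == 0.0:
        raise ValueError("continuous variable is constant")
    n = v.size
    return float((v[mask1].mean() - v[~mask1].mean()) / sn
                 * np.sqrt(n1 * n0 / n ** 2))


def high_state_index(traj: StateTrajectory,
                     threshold: float | str = "median") -> np.ndarray:
    """Posterior probability the latent state exceeds a threshold.

    HAI_k = P(x_k > threshold) = 1 - Phi((threshold - x_{k|K}) / s_{k|K})
    under the smoothed Gaussian posterior.  With threshold="median" the
    threshold is the median of the smoothed means (the person-specific
    baseline).  The same index on a performance trajectory is the HPI.
    """
    means = traj.x_smooth
    sds = np.sqrt(traj.var_smooth)
    if np.any(sds <= 0):
        raise ValueError("non-positive posterior variance")
    if isinstance(threshold, str):
        if threshold != "median":
            raise ValueError(f"unknown threshold '{threshold}'")
        thr = float(np.median(means))
    else:
        thr = float(threshold)
    return stats.norm.sf((thr - means) / sds)
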