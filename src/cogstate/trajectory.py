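"""Latent-state trajectory container shared by all decoders.

Every decoder in this package (arousal from marked-point-process events,
performance from correctness/reaction time, and the performance-based
arousal decoder) produces the same bundle of quantities: one-step
predictions, filtered posteriors, fixed-interval smoothed posteriors, the
observation probability evaluated at the smoothed mean, smoother gains, and
lag-one smoothed cross-moments.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np


@dataclass
class StateTrajectory:
    """Filtered and smoothed moments of a scalar latent state.

    Arrays are indexed by observation (bin or trial).  ``gain`` and
    ``cross_cov`` have one fewer entry: ``gain[k]`` is the smoother gain
    linking index k to k+1 and ``cross_cov[k] = E[x_{k+1} x_k]`` under the
    smoothed posterior.
    """

    x_pred: np.ndarray
    var_pred: np.ndarray
    x_filt: np.ndarray
    var_filt: np.ndarray
    x_smooth: np.ndarray
    var_smooth: np.ndarray
    prob: np.ndarray
    gain: np.ndarray
    cross_cov: np.ndarray

    def __post_init__(self):
        for f in fields(self):
            setattr(self, f.name, np.asarray(getattr(self, f.name), dtype=float))
        k = len(self.x_filt)
        if k == 0:
            raise ValueError("empty trajectory")
        for name in ("x_pred", "var_pred", "var_filt", "x_smooth",
                     "var_smooth", "prob"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"length mismatch in {name}")
        if len(self.gain) != max(k - 1, 0) or len(self.cross_cov) != max(k - 1, 0):
            raise ValueError("gain/cross_cov must have length K-1")
        if np.any(self.var_filt <= 0) or np.any(self.var_smooth <= 0):
            raise ValueError("variances must be positive")
        if np.any((self.prob <= 0) | (self.prob >= 1)):
            raise ValueError("probabilities must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.x_filt)

    @property
    def ex2(self) -> np.ndarray:
        """E[x_k^2] under the smoothed posterior."""
        return self.x_smooth ** 2 + self.var_smooth
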