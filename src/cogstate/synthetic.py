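"""Synthetic n-back experiment generator.

Emulates the study layout the decoders are built for — two music sessions
(calming, then exciting), each with 16 task blocks of 22 two-second
trials, equal numbers of 1-back and 3-back blocks randomly distributed
within each session — and simulates every observation stream with exactly
the statistical structure the decoders assume: a random-walk arousal state
with Bernoulli events and Gaussian marks, an AR(1) performance state with
Bernoulli correctness and lognormal reaction times, and the quadratic
performance-based observation triple.  A renderer closes the loop back to
a raw skin-conductance trace so the deconvolver is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import sigmoid
from .deconvolution import ImpulseTrain, PhasicKernel, SCRecording, build_kernel
from .mpp import MPPArousalParams, MPPSeries
from .pb import PBObservations, PBParams
from .performance import PerfParams


@dataclass
class ExperimentSchedule:
    """Timing and task layout of an n-back experiment.

    Defaults reproduce the study layout: 2 sessions x 16 blocks x 22
    trials (704 trials), 5 s instruction per block, 2 s per trial (0.5 s
    display + 1.5 s response), 10 s rest after each block, an extra 20 s
    rest at each session's halfway mark, and a 120 s break between
    sessions.
    """

    n_sessions: int = 2
    blocks_per_session: int = 16
    trials_per_block: int = 22
    instruction_s: float = 5.0
    trial_s: float = 2.0
    block_rest_s: float = 10.0
    halfway_rest_s: float = 20.0
    session_break_s: float = 120.0
    block_tasks: list = field(default_factory=list)  # 1 or 3 per block
    session_music: tuple = ("calming", "exciting")

    def __post_init__(self):
        for name in ("n_sessions", "blocks_per_session", "trials_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("instruction_s", "trial_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.block_tasks:
            # deterministic alternating layout when no randomization asked
            self.block_tasks = [1 if b % 2 == 0 else 3
                                for b in range(self.n_blocks)]
        if len(self.block_tasks) != self.n_blocks:
            raise ValueError("block_tasks must cover every block")

    @property
    def n_blocks(self) -> int:
        return self.n_sessions * self.blocks_per_session

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def block_stimulus_s(self) -> float:
        return self.instruction_s + self.trials_per_block * self.trial_s

    def trial_windows(self) -> np.ndarray:
        """(K, 2) array of [start, end) times for every trial."""
        out = np.empty((self.n_trials, 2))
        t = 0.0
        k = 0
        half = self.blocks_per_session // 2
        for s in range(self.n_sessions):
            for b in range(self.blocks_per_session):
                t += self.instruction_s
                for _ in range(self.trials_per_block):
                    out[k] = (t, t + self.trial_s)
                    t += self.trial_s
                    k += 1
                t += self.block_rest_s
                if half and b + 1 == half:
                    t += self.halfway_rest_s
            if s + 1 < self.n_sessions:
                t += self.session_break_s
        return out

    @property
    def total_duration(self) -> float:
        last = self.trial_windows()[-1, 1]
        return last + self.block_rest_s

    def trial_frame(self) -> pd.DataFrame:
        rows = []
        k = 0
        for blk in range(self.n_blocks):
            session = blk // self.blocks_per_session
            music = self.session_music[session % len(self.session_music)]
            for _ in range(self.trials_per_block):
                rows.append((k, music, self.block_tasks[blk], blk))
                k += 1
        return pd.DataFrame(rows, columns=["trial", "session", "task", "block"])


def make_schedule(n_sessions: int = 2, blocks_per_session: int = 16,
                  trials_per_block: int = 22, seed: int = 0,
                  **timing) -> ExperimentSchedule:
    """Build a schedule with equal 1-/3-back counts per session, shuffled.

    Raises if the per-session block count is odd (the equal-task
    constraint cannot hold).
    """
    if blocks_per_session % 2:
        raise ValueError("blocks_per_session must be even for equal "
                         "1-back/3-back counts")
    rng = np.random.default_rng(seed)
    tasks = []
    for _ in range(n_sessions):
        sess = [1] * (blocks_per_session // 2) + [3] * (blocks_per_session // 2)
        rng.shuffle(sess)
        tasks.extend(sess)
    return ExperimentSchedule(n_sessions=n_sessions,
                              blocks_per_session=blocks_per_session,
                              trials_per_block=trials_per_block,
                              block_tasks=tasks, **timing)


def simulate_mpp_arousal(params: MPPArousalParams, n_bins: int, seed: int = 0,
                         x0: float = 0.0, bin_width: float = 2.0
                         ) -> tuple[np.ndarray, MPPSeries]:
    """Random-walk arousal with Bernoulli events and Gaussian marks."""
    rng = np.random.default_rng(seed)
    x = x0 + np.cumsum(rng.normal(0.0, np.sqrt(params.sigma_eps_sq), n_bins))
    a = sigmoid(x + params.beta)
    n = (rng.random(n_bins) < a).astype(int)
    r = np.full(n_bins, np.nan)
    ev = n == 1
    r[ev] = (params.gamma0 + params.gamma1 * x[ev]
             + rng.normal(0.0, np.sqrt(params.sigma_v_sq), int(ev.sum())))
    return x, MPPSeries(n, r, bin_width)


def simulate_behavior(params: PerfParams, K: int | None = None,
                      schedule: ExperimentSchedule | None = None,
                      seed: int = 0, z0: float = 0.0
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """AR(1) performance with Bernoulli correctness and lognormal RTs."""
    if schedule is not None:
        K = schedule.n_trials
    if K is None:
        raise ValueError("give K or a schedule")
    rng = np.random.default_rng(seed)
    z = np.empty(K)
    prev = z0
    w = rng.normal(0.0, np.sqrt(params.sigma_w_sq), K)
    for k in range(K):
        prev = params.rho * prev + w[k]
        z[k] = prev
    p = sigmoid(z + params.mu)
    m = (rng.random(K) < p).astype(int)
    tau = np.exp(params.alpha0 + params.alpha1 * z
                 + rng.normal(0.0, np.sqrt(params.sigma_delta_sq), K))
    if schedule is not None:
        frame = schedule.trial_frame()[["trial", "session", "task"]].copy()
    else:
        frame = pd.DataFrame({"trial": np.arange(K), "session": "sim",
                              "task": 1})
    frame["correct"] = m
    frame["rt_s"] = tau
    return z, frame


@dataclass
class SyntheticDataset:
    """Ground truth plus every observation stream for one simulated run."""

    schedule: ExperimentSchedule
    seed: int
    params: PBParams
    x_true: np.ndarray            # performance-based arousal path, per trial
    phi_true: np.ndarray          # event probability along the true path
    obs: PBObservations           # (event, mark, performance) triples

    def impulse_train(self) -> ImpulseTrain:
        """Place one impulse per event trial at the trial midpoint.

        The mark model is Gaussian and can produce negative marks when the
        state is strongly negative; physical sudomotor amplitudes are
        positive, so marks are clamped at a small floor for rendering.
        """
        windows = self.schedule.trial_windows()
        ev = self.obs.n == 1
        times = windows[ev].mean(axis=1)
        return ImpulseTrain(times, np.maximum(self.obs.r[ev], 0.01))


def simulate_pb_dataset(params: PBParams | None = None,
                        schedule: ExperimentSchedule | None = None,
                        seed: int = 0, x0: float = 0.0) -> SyntheticDataset:
    """Simulate the performance-based arousal model over a schedule.

    The arousal state is a per-trial random walk; each trial draws an
    event indicator from the sigmoid-transformed state, a Gaussian mark on
    event trials, and a noisy quadratic performance observation.
    """
    params = params or PBParams()
    schedule = schedule or make_schedule(seed=seed)
    rng = np.random.default_rng(seed)
    K = schedule.n_trials
    x = x0 + np.cumsum(rng.normal(0.0, np.sqrt(params.sigma_u_sq), K))
    phi = sigmoid(x + params.q0)
    n = (rng.random(K) < phi).astype(int)
    z = (params.lambda1 * x ** 2 + params.lambda0
         + rng.normal(0.0, np.sqrt(params.sigma_psi_sq), K))
    r = np.full(K, np.nan)
    ev = n == 1
    r[ev] = (params.gamma0 + params.gamma1 * x[ev]
             + rng.normal(0.0, np.sqrt(params.sigma_zeta_sq), int(ev.sum())))
    obs = PBObservations(n, r, z)
    return SyntheticDataset(schedule=schedule, seed=seed, params=params,
                            x_true=x, phi_true=phi, obs=obs)


def render_scr(impulses: ImpulseTrain, kernel: PhasicKernel | None = None,
               tonic: float = 1.0, noise_sd: float = 0.0, fs: float = 4.0,
               seed: int = 0, duration: float | None = None) -> SCRecording:
    """Render an impulse train into a raw skin-conductance trace.

    Convolution of the impulses with the phasic kernel, plus a constant
    tonic level and white Gaussian sensor noise.
    """
    kernel = kernel or PhasicKernel()
    if duration is None:
        last = impulses.times[-1] if len(impulses) else 0.0
        duration = last + 8.0 * kernel.tau_decay
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("rendered duration too short")
    h = build_kernel(kernel.tau_rise, kernel.tau_decay, fs,
                     min(8.0 * kernel.tau_decay, duration))
    phasic = np.zeros(n)
    for t, a in zip(impulses.times, impulses.amplitudes):
        i = int(round(t * fs))
        if 0 <= i < n:
            li = min(h.size, n - i)
            phasic[i:i + li] += a * h[:li]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    return SCRecording(tonic + phasic + noise, fs=fs)
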