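"""End-to-end pipeline: skin conductance + behavior -> all decoded states.

Stage order: deconvolve the skin-conductance trace, bin the impulses to a
marked point process, EM-decode arousal, EM-decode performance from the
trial table, quantify the arousal-performance link, then run the
performance-based arousal EM decoder on the combined observation.  With a
simulate preset the pipeline first generates all inputs from the bundled
synthetic experiment, so the whole chain runs with no external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from ._util import coefficient_of_determination
from .deconvolution import PhasicKernel, deconvolve, reconstruct_and_score
from .link import (fit_inverted_u, high_state_index, point_biserial,
                   standardize, trial_average_arousal)
from .mpp import bin_to_mpp, mpp_em
from .performance import PerfParams, perf_em
from .pb import build_pb_observations, pb_em
from .synthetic import (make_schedule, render_scr, simulate_behavior,
                        simulate_pb_dataset)

logger = logging.getLogger("cogstate")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Inputs and knobs for one full pipeline run.

    Either ``preset="fig7"`` (simulate everything) or both ``scr_path``
    and ``trials_path`` must be given.
    """

    out_dir: str | Path
    preset: str | None = None
    scr_path: str | Path | None = None
    trials_path: str | Path | None = None
    seed: int = 1
    fs: float = 4.0
    bin_width: float = 2.0
    sparsity: float = 0.05
    noise_sd: float = 0.02
    schedule_kwargs: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.preset is None:
            if self.scr_path is None or self.trials_path is None:
                raise ValueError("need a preset or both scr_path and trials_path")
            for p in (self.scr_path, self.trials_path):
                if not Path(p).exists():
                    raise ValueError(f"input file not found: {p}")
        elif self.preset != "fig7":
            raise ValueError(f"unknown preset '{self.preset}'")
        if self.bin_width <= 0 or self.fs <= 0:
            raise ValueError("bin_width and fs must be positive")


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts plus a JSON report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kernel = PhasicKernel()
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "seed": config.seed}

    schedule = None
    dataset = None
    if config.preset == "fig7":
        logger.info("stage=simulate preset=fig7 seed=%d", config.seed)
        schedule = make_schedule(seed=config.seed, **config.schedule_kwargs)
        dataset = simulate_pb_dataset(schedule=schedule, seed=config.seed)
        scr = render_scr(dataset.impulse_train(), kernel,
                         noise_sd=config.noise_sd, fs=config.fs,
                         seed=config.seed,
                         duration=schedule.total_duration)
        _, trials = simulate_behavior(params=PerfParams(),
                                      schedule=schedule, seed=config.seed + 1)
        io.write_scr_csv(out / "scr.csv", scr)
        io.write_trials_csv(out / "trials.csv", trials)
    else:
        scr = io.read_scr_csv(config.scr_path)
        trials = io.read_trials_csv(config.trials_path)
        schedule = make_schedule(seed=config.seed, **config.schedule_kwargs)

    logger.info("stage=deconvolve n_samples=%d", scr.samples.size)
    impulses = deconvolve(scr, kernel, sparsity=config.sparsity)
    _, r2_scr = reconstruct_and_score(impulses, kernel, scr)
    io.write_impulses_csv(out / "impulses.csv", impulses)
    report["deconvolution"] = {"n_impulses": len(impulses), "r2": r2_scr}

    logger.info("stage=mpp_em n_impulses=%d", len(impulses))
    span = schedule.total_duration
    mpp_obs = bin_to_mpp(impulses, config.bin_width, span)
    mpp_params, mpp_traj, mpp_trace = mpp_em(mpp_obs)
    io.write_trajectory_csv(out / "arousal.csv", mpp_traj, index_name="bin")
    io.write_params_json(out / "arousal_params.json", mpp_params)
    report["mpp"] = {"n_bins": len(mpp_obs), "em_iters": len(mpp_trace),
                     "q_final": mpp_trace[-1]}

    logger.info("stage=perf_em n_trials=%d", len(trials))
    perf_params, perf_traj, perf_trace = perf_em(trials)
    io.write_trajectory_csv(out / "performance.csv", perf_traj,
                            index_name="trial")
    io.write_params_json(out / "performance_params.json", perf_params)
    report["performance"] = {"em_iters": len(perf_trace),
                             "q_final": perf_trace[-1]}

    logger.info("stage=link")
    windows = schedule.trial_windows()
    arousal_per_trial = trial_average_arousal(mpp_traj, windows,
                                              config.bin_width)
    fit = fit_inverted_u(standardize(arousal_per_trial),
                         standardize(perf_traj.x_smooth))
    tasks = schedule.trial_frame()["task"].to_numpy()
    r_pb_task = point_biserial((tasks == 3).astype(int), arousal_per_trial)
    hai = high_state_index(mpp_traj)
    hpi = high_state_index(perf_traj)
    np.savetxt(out / "hai.csv", hai, header="hai", comments="")
    np.savetxt(out / "hpi.csv", hpi, header="hpi", comments="")
    report["link"] = {
        "lambda1": fit.lambda1, "lambda2": fit.lambda2, "lambda3": fit.lambda3,
        "pvalues": fit.pvalues, "n_iter": fit.n_iter,
        "point_biserial_task": r_pb_task,
    }

    logger.info("stage=pb_em")
    pb_obs = build_pb_observations(impulses, perf_traj, windows)
    pb_params, pb_post, q3 = pb_em(pb_obs, max_iters=100)
    io.write_trajectory_csv(out / "pb_arousal.csv", pb_post,
                            index_name="trial")
    io.write_params_json(out / "pb_params.json", pb_params)
    report["pb"] = {"em_iters": len(q3), "q3_final": q3[-1],
                    "lambda1": pb_params.lambda1}
    if dataset is not None:
        report["pb"]["state_r2_vs_truth"] = coefficient_of_determination(
            dataset.x_true, pb_post.x_smooth)

    io.write_report_json(out / "report.json", report)
    return report
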