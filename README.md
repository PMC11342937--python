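# cogstate

Bayesian state-space decoding of hidden **cognitive arousal** and
**performance** during an n-back working-memory task, and of the
inverted-U (Yerkes–Dodson) relationship between them.

Who it is for: researchers in affective computing and physiological
signal processing who record skin conductance and behavioral responses
(correct/incorrect, reaction time) during cognitive tasks and want
continuous latent-state estimates instead of discrete ratings.

## What it computes

1. **Skin-conductance deconvolution** — recovers a sparse train of
   sympathetic (sudomotor) impulses from a raw conductance trace by
   nonnegative ℓ1-penalized coordinate descent against a bi-exponential
   response kernel, with a spline tonic baseline.
2. **Arousal decoder** — a marked-point-process state-space filter: the
   arousal state x_j is a random walk observed through Bernoulli event
   indicators, P(n_j = 1) = σ(x_j + β), and Gaussian event marks
   r_j = γ0 + γ1 x_j + v_j; posterior-mode filtering, fixed-interval
   smoothing, and EM parameter estimation.
3. **Performance decoder** — an AR(1) state z_k = ρ z_{k−1} + w_k
   observed through correctness m_k ~ Bernoulli(σ(z_k + μ)) and log
   reaction time log τ_k = α0 + α1 z_k + δ_k.
4. **Link metrics** — robust (Tukey bisquare) fit of
   Y = λ1 X² + λ2 X + λ3 between standardized trial arousal and
   performance, point-biserial correlation with task difficulty, and
   high-arousal/high-performance indices (HAI/HPI).
5. **Performance-based arousal decoder** — the centerpiece: one
   random-walk arousal state observed *simultaneously* through arousal
   events, their amplitudes, and the performance state via the quadratic
   channel z_k = λ̃1 x̃²_k + λ̃0 + ψ_k, estimated by an EM algorithm with
   an exact grid E-step and closed-form M-steps.
6. **Synthetic experiment** — generates the full 2-session × 16-block ×
   22-trial study layout (704 trials) and every observation stream with
   the exact statistical structure the decoders assume, so the whole
   pipeline is testable with no external data.

See `docs/methods.md` for the models, assumptions, and numerical
choices.

## Worked example

Simulate one full synthetic experiment, decode the arousal state from
its own observations, and compare to the ground truth:

```python
from cogstate import (simulate_pb_dataset, pb_em,
                      coefficient_of_determination, fit_inverted_u,
                      standardize)

dataset = simulate_pb_dataset(seed=1)          # 704 trials
params, posterior, trace = pb_em(dataset.obs)  # EM decode

r2 = coefficient_of_determination(dataset.x_true, posterior.x_smooth)
print(f"state recovery R^2 = {r2:.4f}")
print(f"lambda1 = {params.lambda1:.3f}  gamma1 = {params.gamma1:.3f}")

fit = fit_inverted_u(standardize(posterior.x_smooth),
                     standardize(dataset.obs.z))
print(f"inverted-U curvature {fit.lambda1:.3f}, p = {fit.pvalues[0]:.2e}")
```

Output:

```
state recovery R^2 = 0.9553
lambda1 = -0.981  gamma1 = 0.577
inverted-U curvature -0.285, p = 0.00e+00
```

The decoded arousal path explains ~96% of the variance of the simulated
truth; the estimated quadratic gain λ̃1 ≈ −1 and mark slope γ̃1 ≈ 0.5 sit
near the generating values (−0.8 and 0.5; the state scale is only
weakly identified, see the methods note), and the robust fit on the
decoded states detects the inverted-U with a significantly negative
curvature (the p-value underflows to zero at this sample size).

The same pipeline runs from the shell:

```bash
cogstate simulate --seed 1 --out run/
cogstate deconvolve --in run/scr.csv --sparsity 0.05 --out run/impulses.csv
cogstate decode-performance --trials run/trials.csv --out run/perf.csv
cogstate run --preset fig7 --seed 1 --out run/full
```

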