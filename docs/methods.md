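# Methods

`cogstate` decodes two latent cognitive states during an n-back
working-memory task — sympathetic **arousal**, observed through the skin
conductance signal, and **performance**, observed through trial outcomes —
and quantifies the inverted-U (Yerkes–Dodson) relationship between them.
This note describes the models, the estimation machinery, the numerical
choices, and what the bundled simulations can and cannot establish.

## Skin-conductance deconvolution

The phasic component of a skin-conductance trace is modeled as a sparse
train of sudomotor nerve impulses convolved with a stereotyped
bi-exponential response kernel

    h(t) = c (e^{-t/τ_d} - e^{-t/τ_r}),   0 < τ_r < τ_d,

normalized to unit peak, riding on a slowly varying tonic baseline.
Defaults τ_r = 0.7 s, τ_d = 3.0 s are typical of the skin-conductance
response literature and are configurable. Impulse recovery minimizes the
nonnegative ℓ1-penalized least-squares objective

    ½‖y − tonic − H u‖² + s‖u‖₁,  u ≥ 0,

by cyclic coordinate descent (each sweep is a closed-form soft-threshold
per coordinate; the objective is convex and asserted non-increasing).

The tonic baseline is a shape-preserving cubic (PCHIP) through running
window minima (knot spacing 10 s by default). Two refinements matter in
practice and are part of the method: (i) window minima are debiased by
the expected minimum of Gaussian sensor noise over the window, with the
noise scale estimated robustly from first differences; (ii) after an
initial fit, the baseline is re-estimated from window *medians* of the
phasic-subtracted residual and the fit repeated (three passes). Without
(ii) the running minimum rides up on slow SCR tails and absorbs up to a
quarter of the amplitude of small, late responses. After convergence,
amplitudes below 1% of the maximum are dropped and adjacent-sample runs
are merged by amplitude sum.

Limitations: no motion-artifact handling, no tonic-level (SCL) analysis;
the kernel is a declared simplification, not a fitted physiological
model.

## Arousal from binned impulse events (marked point process)

Impulses are aggregated onto half-open bins (default width 2 s, the trial
length). The hidden arousal state follows a random walk
x_j = x_{j−1} + ε_j, ε_j ~ N(0, σ²_ε). A bin carries an event with
probability a_j = sigmoid(x_j + β), and an event's mark (mean impulse
amplitude) is Gaussian, r_j ~ N(γ0 + γ1 x_j, σ²_v). The one-step
posterior — Gaussian prediction × Bernoulli × (optionally) Gaussian
mark — has a strictly decreasing score in x, so the posterior mode is the
unique root, found by safeguarded bracketing (Brent) on
x_pred ± 10σ_pred. The posterior variance is the inverse observed
information at the mode; the backward pass is the standard fixed-interval
smoother with gain A_j = σ²_{j|j}/σ²_{j+1|j}.

EM estimates (γ0, γ1, σ²_v, σ²_ε) with closed-form M-steps built from the
smoothed moments E[x], E[x²] and the lag-one cross-moment; β stays fixed
at logit(mean event rate). Variance estimates are floored at 1e-8.
Limiting cases are exact and tested: with events on every bin and a
saturated event channel the filter is a Kalman filter on the marks; with
zero mark slope it is the Bernoulli-only filter.

## Performance from correctness and reaction time

The performance state is AR(1), z_k = ρ z_{k−1} + w_k. Each trial yields
a binary correctness m_k ~ Bernoulli(sigmoid(z_k + μ)) and a log reaction
time log τ_k = α0 + α1 z_k + δ_k. The sign convention is that higher
performance means faster responses, so α1 is expected negative; it is
initialized at −0.1 but not constrained. μ is fixed at logit(mean
correct rate), clipped to [1/(2K), 1 − 1/(2K)] for degenerate sequences.
The filter is the same posterior-mode update with a linear continuous
channel; the smoother gain carries the extra ρ factor; the stationary
prior z0 = 0, var0 = σ²_w/(1−ρ²) is used when |ρ| < 1. Trials without a
response are coded incorrect with missing reaction time, and the update
then uses the Bernoulli term only. EM estimates (α0, α1, σ²_δ, ρ, σ²_w)
in closed form, with ρ clamped to [−1, 1].

## Arousal–performance link

Per-trial arousal is the mean smoothed state over the bins whose centres
fall in the trial window. Both series are standardized with the
population standard deviation over the whole experiment, and the
inverted-U model

    Y_k = λ1 X_k² + λ2 X_k + λ3 + e_k

is fitted by iteratively reweighted least squares with Tukey bisquare
weights (tuning constant 4.685, scale = MAD/0.6745 re-estimated every
iteration, convergence at 1e-8 or 100 iterations). On clean data all
weights are 1 and the fit reduces to ordinary least squares.
Per-coefficient p-values come from t statistics of the final weighted
least-squares step with n − 3 degrees of freedom. Task difficulty vs
arousal uses the point-biserial correlation (population-sd formula,
identical to Pearson with 0/1 coding). The high arousal index (HAI) is
the posterior probability that the smoothed state exceeds a threshold,
HAI_k = 1 − Φ((thr − x_{k|K})/σ_{k|K}), with the person-specific median
of the smoothed means as the default threshold; the same operation on the
performance trajectory is the HPI.

## Performance-based arousal decoder

The central model: a per-trial random-walk arousal state x̃_k observed
simultaneously through (i) a Bernoulli event indicator
ñ_k ~ Bernoulli(sigmoid(x̃_k + q0)), (ii) on event trials a Gaussian mark
r̃_k ~ N(γ̃0 + γ̃1 x̃_k, σ²_ζ), and (iii) the performance state through an
inverted-U quadratic z_k = λ̃1 x̃²_k + λ̃0 + ψ_k. The z input is the
*smoothed* performance state from the performance decoder.

**Per-trial update.** The one-step score adds the quadratic channel's
term 2λ̃1 x (z − λ̃0 − λ̃1 x²)/σ²_ψ, which can make the one-step posterior
bimodal. `pb_filter_step` scans the score on a grid over x_pred ± 10σ,
refines every sign change by Brent's method, and keeps the root nearest
the prediction (path continuity); the Laplace variance uses the observed
information at the mode, falling back to the prediction variance when the
information bracket is non-positive (the Laplace approximation is invalid
there, and the prediction variance is the conservative choice). Fourth
moments use E[x⁴] = (E[x²])² + 4 m² s² + 2 s⁴, which is exact for a
Gaussian; the smoothed variance enters by default
(`moment_variance="filtered"` switches to the filtered one).

**Why the EM E-step is a grid, not the Laplace recursion.** Three
structural hazards were identified on simulated data at the default
generating parameters:

1. *Reflection*: the mark and quadratic channels are exactly invariant
   under x → −x with γ̃1 → −γ̃1; only the event channel breaks the
   symmetry, weakly.
2. *Scale ridge*: they are likewise exactly invariant under x → cx with
   γ̃1 → γ̃1/c, λ̃1 → λ̃1/c², σ²_u → c²σ²_u; the event channel is again
   the only anchor.
3. *Variance collapse*: with mode-curvature (Laplace) posterior
   variances, the expected complete-data objective is unbounded along
   σ²_u → 0, |λ̃1| → ∞ — the mode path interpolates z and EM runs away.
   A bootstrap particle filter confirmed the true marginal likelihood
   does not support that collapse; it is an artifact of understating
   posterior uncertainty.

Because the state is scalar, an essentially exact E-step is affordable:
`pb_grid_estep` discretizes the state onto 301 points (span derived from
the amplitude the quadratic channel implies), runs forward–backward
recursions with a Gaussian random-walk transition, and returns exact
marginals, exact second/fourth moments, lag-one cross-moments, and the
exact marginal log-likelihood. With this E-step the EM objective is
monotone by construction and none of the three hazards bites. The
Laplace recursion remains available (`e_step="laplace"`) and is what the
per-trial update functions implement.

**The event offset q0.** Approximating q0 by logit(mean event rate) is
accurate only when the state hovers near zero. Under the default
generating parameters the random walk wanders several units, the
realized event rate is dominated by where the path happened to go, and
the fixed-q0 model is misspecified in a way that makes *rescaled* state
paths genuinely likelihood-preferred (verified with unbiased
particle-filter likelihood estimates). The M-step therefore updates q0
by a concave Newton step on its expected log-likelihood term — the
quadratic channel pins |x̃|, so q0 is cleanly identified.
`estimate_q0=False` restores the fixed-offset behavior.

**Multi-start and selection.** The scale direction remains weakly
identified (hazard 2), so with no explicit initialization `pb_em` runs
EM from three moment-matched starts at quadratic gains
λ̃1 ∈ {−0.3, −1, −3} (λ̃0 from the upper envelope of z; the state's mean
square, σ²_u, and γ̃1 scaled consistently) and selects by marginal
log-likelihood, with one tie-break: among runs within 5 nats of the
best, prefer the one whose logistic regression of events on the decoded
state has slope nearest 1 (internal calibration of the event channel).
Convergence is declared when the largest relative parameter change drops
below 1e-4 (default cap 30 iterations per start).

## Synthetic experiment

The generator reproduces the study layout — 2 music sessions (calming
then exciting) × 16 blocks × 22 trials = 704 trials; 5 s instruction and
2 s per trial (49 s stimulus per block); 10 s block rests, 20 s halfway
rests, 120 s between sessions; equal 1-back/3-back counts per session,
shuffled by seed — and simulates every observation stream with exactly
the statistical structure the decoders assume. Default generating
parameters for the performance-based model are σ²_u = 0.05, φ0 = 0.3,
λ̃1 = −0.8, λ̃0 = 1, σ²_ψ = 0.2, γ̃0 = 0.5, γ̃1 = 0.5, σ²_ζ = 0.1; the
arousal/behavior generators default to σ²_ε = 0.05, a0 = 0.3,
γ = (0.5, 0.5), σ²_v = 0.1 and ρ = 0.99, σ²_w = 0.01, p0 = 0.8,
α = (0, −0.3), σ²_δ = 0.04. All values are package choices selected to
produce visibly structured paths at desk scale and are overridable.
Every generator is reproducible bit-for-bit from (seed, parameters).

A renderer closes the loop to a raw skin-conductance trace (one impulse
per event trial at the trial midpoint, convolved with the phasic kernel,
plus tonic level and white sensor noise), so the deconvolver is testable
end to end. Negative Gaussian marks are clamped at 0.01 before rendering
(physical amplitudes are positive).

What the simulations do **not** emulate: motion artifacts and electrode
drift in real electrodermal recordings, learning and fatigue trends in
behavior, session-level arousal shifts induced by the music, and
participant heterogeneity. Passing the bundled tests therefore shows the
estimation machinery is correct under the model's own assumptions, not
that the model captures every feature of real recordings.

## Problem sizes and runtime choices

Recovery checks use the full experiment size (K = 704 trials) with 10–20
replicates, the binned arousal EM uses J = 1000 bins with 10 replicates,
and the inverted-U detection check uses 50 replicates; these sizes give
stable medians while keeping the full suite comfortably runnable on one
CPU. EM iteration caps (30 for the performance-based decoder, 40–50 for
the others) sit past the observed convergence plateau at these sizes.

## Known limitations

- On realizations where the random walk drifts so far that the event
  channel saturates (events nearly absent or nearly constant), the state
  scale is close to unidentifiable and the likelihood can prefer a
  rescaled solution; the multi-start selection then picks a wrong-scale
  run on a minority of seeds. The median-over-replicates recovery
  quality is unaffected, but individual runs can be poor.
- The per-trial Laplace update's nearest-root policy is a continuity
  heuristic; under strong bimodality it can differ from the global
  posterior mode (logged in the oracle tests as a policy, not an error).
- The robust-fit p-values are final-iteration weighted-least-squares t
  tests, adequate for detection at these sample sizes but not corrected
  for the two-stage (decode-then-regress) uncertainty.
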