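# Methods

## The measurement model

The package treats a session as three synchronised streams: a
calcium-dependent fluorescence channel `s(t)` (473 nm excitation,
500 Hz), an isosbestic control `c(t)` (405 nm, calcium-independent),
and a 30 Hz pose track whose neck point gives the allocentric movement
speed. The scientific object is the relationship between the z-scored
ΔF/F of a cholinergic population and the logarithm of movement speed —
its slope, its dependence on lighting and behavioural state, and its
temporal resolution.

### Isosbestic correction

Both channels are averaged within TTL-delimited frame windows
(`[t_i, t_{i+1})`, last window = median inter-frame interval). The
correction follows the standard recipe: fit a 2nd-degree polynomial to
`d = s − c` over time (centred/scaled internally for conditioning),
add it to the control, fit `(α, β)` by closed-form least squares
(`α = cov(c, s)/var(c)`), and form `ΔF/F = (s − (cα+β))/(cα+β)` with a
denominator guard of `1e-6 × median|cα+β|`. z-scoring uses the sample
(n−1) SD within one session; per-session z-scoring is adopted because
cross-session comparisons are explicitly the reason for normalising.

A property of this recipe worth knowing: the polynomial step absorbs
whatever part of the *signal* is well-approximated by a quadratic in
time. Short sessions with little fast signal variance therefore lose a
larger fraction of true ΔF/F to the control adjustment. On synthetic
sessions the recovered ΔF/F correlates ≥ 0.9 with ground truth in
18/20 default (300 s) sessions; at 120 s the tail widens. This is a
limitation of the published method itself, reproduced deliberately.

### Kinematics

Speed is the frame-to-frame displacement of the neck point times the
frame rate, with `speed[0] = speed[1]`. No positional smoothing is
applied by default (an optional 3-frame median filter exists), since
the generator's jitter-error bound is already met without it.
`log₂` speed uses a floor ε = 0.25 cm/s — roughly one pixel of tracking
jitter per frame — because zero speeds otherwise map to −∞; ranks above
the floor are preserved exactly. Frames below 3 cm/s are stationary;
sessions stationary for strictly more than 2/3 of their frames form the
stationary-activity subset.

## The synthetic-session generator

The generator is first-class code: it defines the study conditions under
which every statistical claim of the package is tested.

- **Behaviour**: five states (still, exploratory walking, exploratory
  running, grooming, rearing) drawn i.i.d. with probabilities
  ∝ occupancy/mean-dwell and log-normal dwell times (state-specific
  medians, σ = 0.6), so long-run occupancies equal their targets. The
  default occupancies are the published open-field fractions
  (70.4% running, 26.2% walking, 2.1% rearing, 1.4% grooming),
  renormalised from their rounded sum of 100.1%.
- **Trajectory**: per-bout target speeds drawn uniformly from the
  state's range (run 10–30, walk 3–10, stationary states 0.2–2 cm/s), a
  mean-reverting fluctuation around the target (τ = 0.5 s), clipping to
  the state range, a diffusing heading, and triangle-fold reflection at
  the 40 × 40 cm walls. Written pose tracks add Gaussian jitter
  (0.05 cm/coordinate) and ~2% low-likelihood dropout frames with
  inflated error, which the pipeline interpolates away.
- **Latent activity** (z-ΔF/F scale):
  `β₀ + (β₁ + b₁)·log₂ max(v, ε) + β_rear·I[rear] + β_groom·I[groom] +
  β_ER·I[run] + darkness terms + b₀ + AR(1) noise`, with per-animal and
  per-session random intercepts/slopes. Default coefficients are the
  published point estimates (β₁ = 0.221, β_rear = 0.277, …); darkness
  effects default to zero, mirroring the null finding.
- **Noise budget**: the unexplained variance is split into a slow AR(1)
  latent component (marginal SD 0.5, lag-1 coefficient 0.9 at 30 Hz)
  that *does* pass the indicator kernel, and a fast white readout
  component (SD 0.6 z at the frame clock) that does not. Both together
  give a realistic residual SD ≈ 0.78 on a z-scaled response. The split
  matters for the integration-window analysis: if all unexplained
  variance were kernel-filtered, longer boxcar windows would keep
  paying off indefinitely and the optimal window would not discriminate
  indicator kinetics.
- **Optical render**: the latent trace is scaled to ΔF/F (0.05 per
  z-unit + 0.05 offset), convolved with a causal
  difference-of-exponentials kernel whose decay constant is solved
  numerically so the peak-to-half-peak time equals the configured
  half-decay (default 1.69 s, the indicator's published value; rise
  τ = 0.2 s is a free parameter typical of slow indicators), multiplied
  onto an exponentially bleaching baseline (473: 2.0 a.u., τ = 600 s;
  405: 1.0 a.u., τ = 500 s), and contaminated with Poisson-timed
  exponential motion transients shared across channels with gain
  γ = 0.8 plus white noise (SD 0.01 a.u. per sample).

### Readout levels

`simulate_aligned_session(response=...)` exposes three readouts:
`"model"` (latent + fast noise; the scale on which the mixed-model
coefficients are defined), `"kernel"` (z-scored kernel-convolved latent
+ fast noise; used for temporal-dynamics and causality studies), and
`"photometry"` (full optical render + complete preprocessing).
Parameter-recovery studies use the model scale deliberately: the
indicator kernel and per-session z-scoring are measurement distortions
that the statistical models do not invert, so demanding unbiased
coefficient recovery through them would be ill-posed. Fidelity of the
optical chain is validated separately (ΔF/F recovery ≥ 0.9 correlation;
artifact-rejection ≥ 4×; isosbestic channel carries no calcium signal).

What the generator does **not** emulate: carrier-frequency modulation
and lock-in demodulation, hemodynamic contamination, heading-dependent
pose occlusions, non-exponential bleaching, estrous-state effects, and
real VAME/DeepLabCut segmentation noise (labels are emitted as truth).
Passing tests therefore validate the analysis machinery under the
stated generative assumptions, not those upstream acquisition steps.

## Window scan

Only the activity trace is smoothed (the speed trace is not), with
centred odd-width boxcars and truncated edges; correlation is computed
against unsmoothed `log₂ v` over a grid of 1 frame to 10 s in 1-frame
steps; ties in the argmax resolve to the smallest window. The centred
(rather than causal) window reflects the correlation framing of the
analysis, not prediction. The reference window for light/dark t-tests
defaults to 1.3 s.

## Granger causality

Implemented from first principles: stacked multi-trial OLS without
cross-trial lag leakage, per-equation residual covariance with
denominator `n_eff − 2p − 1`, AIC order selection (`p_max = 30` ≈ 1 s
at 30 Hz) on a common effective sample, magnitude
`ln(SSR_reduced/SSR_full)` on identical samples (clipped at 0), and
χ² likelihood-ratio significance (`n·F ~ χ²(p)`). Channels are
mean-removed per trial; sessions shorter than 5 min are used whole with
a warning. Correctness anchors: a closed-form VAR(1) value, a
brute-force regression oracle at n = 10⁶, null calibration (rejection
rate 0.03–0.07 at α = 0.05 over 400 replicates), and the directional
asymmetry (speed → activity > activity → speed) on speed-driven cohorts.

## Mixed models

Fits use statsmodels `MixedLM`, REML by default, with residual-DF
t-tests and Wald CIs (the published tables' enormous DFs indicate
residual-DF inference; Satterthwaite is out of scope). Model-specific
structures:

- speed models: fixed `{1, log₂v, log₂v×dark}`, random intercept+slope
  per animal, random intercept per session. Session random slopes are
  omitted for tractability — fixed effects remain unbiased; the SE cost
  is a few percent.
- behaviour model: fixed `{1, log₂v, dark, ER, rear, groom}` (walking
  as reference), random intercepts for animal and session. The source
  formula also lists random intercepts for darkness (2 levels) and
  community (4 levels); these are not jointly identifiable with the
  fixed effects for the same factors and empirically shrink them toward
  zero (confirmed with an independent lme4 fit), so they are dropped.
- GC-direction model: fixed `{1, direction, dark, direction×dark}` on
  per-session GC magnitudes, random intercepts for animal and session.

Optimisation always runs lbfgs followed by a warm-started Powell
refinement and keeps the better restricted likelihood — lbfgs alone
occasionally reports convergence several log-likelihood units short on
flat surfaces, which broke session-relabelling invariance.

Rows are thinned to ~1 s spacing before fitting (`sessions_to_frame`),
so the AR(1) latent noise is nearly independent between retained rows,
as the model's error term assumes (lag-30 autocorrelation 0.9³⁰ ≈ 0.04).

### Recovery studies

`recovery_study` simulates cohorts, refits, and reports bias, RMSE,
CI coverage and Monte-Carlo SEs per coefficient. Each published table
defines its own generative truth (`achdyn.studies`): the open-field
speed model's truth carries no behaviour offsets (refitting a 3-term
model on data generated with rearing/grooming offsets is biased by
construction — omitted variables concentrated at low speeds); the
behaviour model's truth carries no random slopes, because its published
formula lists random intercepts only. Study problem sizes — 12
replicates of 5 animals × 10 × 5-min sessions for the speed model, 16
replicates of 3 × 8 stationary-dominated sessions, 24 replicates of
3 × 10 × 10-min sessions for the behaviour model, and 100 scaled
replicates (5 × 4 × 2-min) for CI-coverage calibration — were chosen to
hold Monte-Carlo SEs well below the coefficients while keeping the full
recomputation around a minute.

## Numerical conventions

- Tuning bins are half-open `[kw, (k+1)w)`; edge values go up; bins
  with fewer than 5 points are reported empty; SEM = SD/√n.
- Pearson's r of a zero-variance response is defined as 0 with a
  warning.
- The saturating exponential is fitted by multi-start nonlinear least
  squares (τ ∈ {1, 5, 20} cm/s), best SSE wins.
- 1-s scatter sampling takes the single nearest frame per second, not a
  1-s mean.
- Degenerate inputs raise: empty frame windows (named), near-zero ΔF/F
  denominators (frames listed), constant traces, zero-variance
  regressors, all-dropout pose tracks, singular VAR designs.
- All randomness flows through `numpy.random.Generator` seeded
  explicitly; identical (config, seed) pairs give byte-identical output
  files.

## Known limitations

- Absolute values of per-session correlations, optimal windows and GC
  magnitudes depend on the generator's noise composition and behaviour
  kinetics and are not calibrated to any particular recording system;
  ordinal and recovery properties are the validated claims.
- With 3–5 animals, between-animal variance components are estimated on
  very few degrees of freedom; CI coverage of the log-speed slope is
  calibrated (88–99%) but intercept CIs can undercover.
- The stationary-session filter selects on realized behaviour, so
  stationary-cohort sizes vary slightly across replicates.
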