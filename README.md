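# achdyn

Analysis pipeline for the temporal dynamics of cholinergic population
activity versus movement speed in freely moving mice, as measured by
dual-channel fiber photometry (473 nm calcium-dependent + 405 nm
isosbestic control) combined with markerless pose tracking — plus a
synthetic-session generator with known ground truth that turns every
stage of the analysis into a testable parameter-recovery problem.

## Who this is for

Behavioural neurophysiologists working with fiber-photometry recordings
of neuromodulatory populations (e.g. cholinergic neurons of the medial
septum / diagonal band) in open-field tasks, and methodologists who want
a reference implementation of the standard analysis chain with
calibration studies attached.

## The science

**Preprocessing.** Raw 500 Hz channels are resampled to the 30 Hz video
frame clock (TTL-timed within-window means). Photobleaching and motion
artifacts are removed with the isosbestic control: a 2nd-degree
polynomial is fitted to `s − c` over time and added to the control, then
`(α, β)` minimise `Σ (s − (cα + β))²`, and

```
ΔF/F = (s − (cα + β)) / (cα + β),   z-ΔF/F = (x − x̄)/s_x  per session.
```

**Speed tuning.** Allocentric neck speed `v` (cm/s, frame-differenced
pose) relates to activity log-linearly: `z ≈ β₀ + β₁ log₂ max(v, ε)`, a
relationship that extends below the locomotion threshold into stationary
neck movements (< 3 cm/s). A saturating exponential
`z = y∞ − A e^{−v/τ}` is fitted for comparison on the raw-speed axis.

**Temporal dynamics.** For each session the activity trace is smoothed
with centred boxcar windows of increasing width; the window maximising
Pearson's r against `log₂ v` is the session's optimal integration
window. Light and dark sessions are compared with a pooled-variance
t-test (r at a reference window) and a two-sample Kolmogorov–Smirnov
test (optimal-window distributions).

**Granger causality.** Bivariate VAR models of `(log₂ v, z)` are fitted
by OLS on lagged designs stacked across an animal's sessions (multi-trial,
first 5 min each, no lag leakage across trials), order selected by AIC.
The magnitude is `F = ln(SSR_reduced / SSR_full)` per direction, with
`n·F ~ χ²(p)` significance.

**Mixed models.** REML linear mixed-effects models with animal and
session random effects quantify the log-speed slope, its darkness
interaction, and behaviour-community offsets (exploratory running,
rearing, grooming vs. walking). `recovery_study` simulates cohorts from
configured coefficients and reports bias, RMSE and CI coverage.

**The generator** produces semi-Markov behaviour sequences (log-normal
dwells, configurable occupancies), bounded mean-reverting open-field
trajectories with tracking jitter, a latent activity trace that is linear
in log₂-speed with behaviour offsets and AR(1) noise, and a full optical
render: difference-of-exponentials indicator kernel (half-decay 1.69 s
by default), exponential bleaching per channel, shared sparse motion
artifacts, and white measurement noise.

## Worked example

```python
import numpy as np
from achdyn import simulate, tuning, dynamics

cfg = simulate.SynthConfig(session_duration=300.0)
session, truth = simulate.simulate_aligned_session(cfg, seed=0, response="photometry")

x, z = tuning.sample_interval(session.logspeed, session.zdff, session.frame_time, 1.0)
slope, intercept, r = tuning.fit_linear_log(x, z)
print(f"log2-speed tuning: slope={slope:.3f} z per log2(cm/s), r={r:.2f}")

grid = dynamics.default_window_grid(30.0, 10.0)
scan = dynamics.window_scan(session.zdff, session.logspeed, grid, 30.0)
print(f"optimal integration window: {scan.optimal_window:.2f} s "
      f"(r={scan.r_per_window.max():.2f})")

r_rec = np.corrcoef(session.zdff, truth.render.true_dff)[0, 1]
print(f"dF/F recovery vs ground truth: r={r_rec:.2f}")
```

prints

```
log2-speed tuning: slope=0.378 z per log2(cm/s), r=0.35
optimal integration window: 5.87 s (r=0.41)
dF/F recovery vs ground truth: r=0.94
```

The recovered ΔF/F correlates 0.94 with the generator's ground truth.
The tuning slope is steeper than the generating coefficient 0.221
because per-session z-scoring rescales the response by the session SD;
coefficient-recovery studies therefore fit on the model-scale response
(`response="model"`), where the slope is recovered unbiasedly (see
`achdyn.studies`). Smoothing the activity trace improves its correlation
with log-speed up to an optimal window that grows with the indicator's
half-decay.

There is also a CLI over the file-level pipeline:

```
achdyn --seed 1 simulate --n-animals 3 --sessions-per-animal 4 --outdir cohort
achdyn validate cohort/manifest.csv
achdyn all cohort/manifest.csv
```

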