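# Methods

## Task design

The five composed target trajectories are fully determined by their
Fourier coefficients. The published constraint set — 0.25 kg start
value held for the first 3 s, waveform bounded to [0.06, 0.4] kg, value
continuity between each random half and the shared repeat half, and
approximate slope continuity at the junction — does not pin down a
unique coefficient table, so `solve_coefficients` derives a fresh
feasible set: the two equality constraints are solved linearly for b₀
and b₁ of each random line, and the inequality constraints (range, the
[−5, 5] coefficient box, slope match) are satisfied by seeded rejection
sampling with a 10⁵-draw cap. Any feasible set is functionally
equivalent for the downstream scoring pipeline, which only ever sees
the composed 230-sample trajectories.

Numerical choices:

- **Coefficient scale.** Raw coefficients live in [−5, 5] "display"
  units with a fixed scale factor of 10⁻¹ to kg. A smaller scale
  (10⁻²) is incompatible with the box: the 0.25 kg start value forces
  b₀ + Σbₙ = 0.25/scale, which exceeds 5 unless scale ≥ ~0.05.
- **Slope-match tolerance** for the junction condition: 0.005 kg per
  sample step (the condition is stated only as approximate).
- **Junction steps.** Both junctions are exact in the function sense
  (the hold level *is* the random line's phase-0 value; the boundary
  values of the two halves are equal by construction), so the
  one-sample step across a junction is an ordinary waveform increment;
  the validator bounds it at 0.025 kg.
- **Indexing.** Sample index k is 1-based (k = 1…230) to match the
  piecewise definition; file exports also carry t = (k−1)·ΔT seconds.
- Harmonic draws roll off as 1/n, giving smooth, trackable lines;
  random lines keep a 0.002 kg interior margin on the force range so a
  4-decimal file round-trip cannot push a sample out of bounds.

The trial schedule fixes the published first three blocks
(4-3-1-3-4, 1-2-2-4-1, 5-1-5-4-4) and fills the remaining seven blocks
with seeded uniform draws over tasks 1–5; it is identical for every
participant in a run.

## Scoring

AGF is the mean absolute target-measured difference over exactly the
100 samples of a half; the 30 preparation samples never enter any
score. Block means average exactly 5 trials with no outlier exclusion
(none is specified for the original protocol), and learning rates are
computed from blocks 1 and 10 only. A zero block-10 mean raises an
explicit error rather than being epsilon-guarded: it cannot occur with
a noisy quantized device, and clamping would silently bias the rate.
Scores are kept at full precision internally; 4-decimal (kg) and
1-decimal (%) rounding applies only when writing files.

## Synthetic cohort model

Each virtual participant tracks the target with an additive error
process whose amplitude decays exponentially across trials, separately
per half:

    e_t(h) = einf_h + (e0_h − einf_h) · r_h^(t−1),   t = 1…50

The within-trial error is unit-variance low-pass-filtered Gaussian
noise (2nd-order Butterworth, ~1 Hz cutoff at the 10 Hz sampling rate —
human corrective movements are band-limited), scaled by e_t(h), plus a
small white sensor-noise floor (0.001 kg), an optional pursuit lag and
gain (defaults 0 samples and 1.0), then quantized to the 1.6×10⁻³ kg
grid and clipped to 0–0.5 kg. Exponential decay is the simplest
monotone learning curve consistent with error decreasing over blocks.

Because the mean absolute residual is proportional to e_t, a
participant's *expected* learning rate follows in closed form from
(e0, einf, r), with the expected block-j error scale

    ē_j = einf + (e0 − einf) · r^(5(j−1)) · (1 + r + r² + r³ + r⁴)/5.

Group presets are therefore parameterised in learning-rate space: a
participant's expected LR per half is drawn from a correlated bivariate
normal (ρ = 0.5 between halves, truncated at −80%), and e0 is obtained
by inverting the closed form at the participant's own einf (log-normal,
median 0.015/0.012 kg for the random/repeat halves, log-SD 0.35) and
the preset's decay r (0.93 per trial). The default presets target the
four reported cohort means and SDs: NC 34.6 ± 36.9 (random) and
71.8 ± 47.4 (repeat); MCI 30.8 ± 32.4 and 28.5 ± 32.5 (%).

**Calibration** is empirical, in two deterministic pilot stages
(n = 600, internal seed, independent of user seeds): a homogeneous
pilot measures the trial-noise LR variance (so the population spread is
set to make *total* cohort LR SD match the target), and a heterogeneous
pilot measures the small curvature-dependent bias between closed-form
and realized cohort-mean LR (ratio nonlinearity, quantization,
clipping, the sensor-noise floor), which is compensated by shifting the
sampler centre. Proportionality between error scale and AGF is thereby
verified, not assumed.

**Moment matching.** By default a simulated cohort's drawn expected
learning rates are centred and rescaled so their sample mean and SD
equal the preset's calibrated values exactly — a stratified design that
makes a single seeded cohort representative of its preset (cohort-mean
recovery error is then dominated by trial noise, ≈2 pp SD, rather than
participant sampling, ≈6–7 pp at these n). The trade-off: participants
are no longer independent, and two same-preset cohorts are far more
similar than iid sampling would produce, so rank tests comparing them
become extremely conservative. Analyses that need the iid sampling
model classical tests assume (e.g. verifying type-I error of the
engine) should pass `moment_match=False`; the type-I rate of the
between-group test is then at its nominal 5% (measured 5.8% over 500
replicates).

What the generator does *not* emulate: real within-trial error spectra
(unknown for the original participants), visuomotor delay dynamics,
fatigue, attention fluctuations, or any biomechanical hand model.
Passing tests demonstrate that the pipeline recovers the statistical
structure this generative model encodes — not that the model describes
real MCI behaviour.

## Statistics

- **Normality screening**: Shapiro-Wilk per variable, report-only.
- **Split-plot RM-ANOVA** on block-wise mean AGF: within factors block
  (10) × task (random/repeat), between factor group. The engine uses
  the classical stratum decomposition for a design balanced within
  subjects with possibly unequal group sizes; sums of squares within
  each stratum are Type III (model comparison under sum-to-zero
  coding), matching R `car::Anova(type = 3)` with `contr.sum` and SPSS
  GLM conventions — verified against R on a seeded fixture to printed
  precision. Greenhouse-Geisser ε and Mauchly's test are computed from
  the pooled within-group covariance of orthonormal within-effect
  contrasts; Mauchly's p uses the textbook second-order chi-square
  correction (R's `mauchly.test` differs in the ~4th decimal due to a
  dimensional quirk in one correction term). Corrected and uncorrected
  p are both reported; the GG correction raises p for effects anywhere
  near significance, but for small F (far from any decision boundary)
  the df shrinkage can lower p slightly — R and SPSS behave
  identically, and the package does not clamp.
- **Rank tests**: Mann-Whitney U between groups, Wilcoxon signed-rank
  within group, two-sided, α = 0.05, no multiplicity correction.
  Exact enumeration for small untied samples, otherwise average ranks
  with normal approximation and continuity correction. The reported
  "95% CI" is a seeded bootstrap percentile interval (10⁴ resamples)
  for the mean difference: the original analysis names a credible
  interval once but describes no Bayesian machinery, so a
  distribution-free interval for the same quantity is the design
  choice here.
- Degenerate inputs (constant samples, all-tied ranks, all-zero paired
  differences) raise explicit errors rather than returning numbers.

## Problem sizes and determinism

Default cohorts are 40 NC / 28 MCI participants × 50 trials × 230
samples. Monte-Carlo checks use 100 replicates (ANOVA interaction
detection) and 500 replicates (type-I error), sizes at which binomial
error bands are a few percentage points. Every stochastic step derives
from one master seed via named child streams (cohort parameters,
per-participant traces, bootstrap), so identical configs give
byte-identical outputs; preset calibration uses its own fixed internal
seed and is independent of run seeds.

## Known limitations

- The solver-derived coefficient set reproduces the published
  *constraints*, not the published waveform shapes; absolute AGF levels
  are therefore comparable only within a task set.
- The generative model is a stand-in by construction: only block-level
  means and learning-rate distributions of the original cohorts are
  public, so the within-trial noise model is unverifiable.
- Demographics, clinical instruments (MMSE, CDR, etc.) and discriminant
  modelling are out of scope; group labels are carried as plain
  strings.
- The exact F values of the original repeated-measures analysis were
  not published; the ANOVA is validated against independent statistical
  references instead, and the simulation-based check asserts only the
  significance *pattern* (three-way interaction detected in the
  majority of replicates).
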