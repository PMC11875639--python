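# gripletrack

Motor-learning assessment from grip-force pursuit tracking, for
researchers studying early cognitive decline. Older adults with mild
cognitive impairment (MCI) show a selective deficit in *internal*
attention — learning a repeated movement pattern — while *external*
attention (reactive tracking of unpredictable targets) is preserved.
`gripletrack` implements the complete evaluation pipeline around that
idea: design of the dual-structure tracking tasks, tracking-error
scoring and learning-rate variables, group statistics, and a calibrated
synthetic-cohort simulator so the whole pipeline is testable without
the grip device or participants.

## The task and its evaluation variables

Each 23 s trial displays a target force trajectory sampled at
ΔT = 0.1 s (k = 1…230): a 3 s hold at 0.25 kg, a 10 s **random half**
(one of five waveforms, externally driven tracking) and a 10 s
**repeat half** that is identical in every trial (implicitly learnable
pattern). Both halves are 6-harmonic Fourier series with fundamental
ω = 2π/18 rad/s,

f(k) = b₀ + Σₙ₌₁⁶ [aₙ sin(nωkΔT) + bₙ cos(nωkΔT)],

bounded to 0.06–0.4 kg and constrained so the two halves join
continuously in value and approximately in slope. A session is 50
trials (10 blocks × 5 trials, 30 s rest between blocks).

The tracking score of a trial half is the **AGF** (adjustability for
grasping): the mean absolute difference between target and measured
force over that half's 100 samples, in kg. Block means ȦGFʲ average 5
trials, and the **learning rate** per half is

LR = (ȦGF¹ − ȦGF¹⁰) / ȦGF¹⁰ × 100 [%],

computed separately as LR_Ran and LR_Rep. The group signature: LR_Rep
collapses in MCI while LR_Ran does not.

The simulated grip device mirrors the sprung-ring sensor: 0–0.5 kg
range, 1.6×10⁻³ kg resolution, 4.82×10² N/m spring (a 4.92×10⁻² kg
load deforms it 1 mm).

## Worked example

```sh
python examples/03_simulate_cohorts.py
```

```
NC  (n=40): LR_Ran =  36.9 ± 38.0 %   LR_Rep =  71.9 ± 45.2 %
MCI (n=28): LR_Ran =  31.0 ± 34.6 %   LR_Rep =  30.0 ± 34.6 %
```

Two cohorts are simulated from the calibrated group presets and pushed
through the scoring pipeline. Random-half learning is similar in both
groups (≈35%), while repeat-half learning collapses from ≈72% (normal
cognition) to ≈30% (MCI) — the internal-attention deficit the task is
designed to expose. `examples/04_group_statistics.py` then runs the
analysis plan on the same cohorts:

```
between-group lr_ran: p = 0.7039, 95% CI of MCI-NC mean difference = [-23.3, 10.9] %
between-group lr_rep: p = 5.852e-05, 95% CI of MCI-NC mean difference = [-60.8, -23.6] %
within-NC repeat vs random: p = 0.0001815
RM-ANOVA block*task*group: F = 5.06, GG-corrected p = 0.01109
```

Only the repeat-half rate separates the groups, and the three-way
block × task × group interaction confirms the group-specific time
course.

The other examples cover task design (`01`), scoring one participant
(`02`) and the reproducible end-to-end pipeline (`05`). A thin CLI
wraps the same stages: `gripletrack gen-tasks | simulate | score |
analyze | run-all`.

## Layout

- `src/gripletrack/tasks.py` — target-line solver, composition, validation, schedule
- `src/gripletrack/scoring.py` — AGF scores, block means, learning rates
- `src/gripletrack/cohort.py` — device model, virtual participants, preset calibration
- `src/gripletrack/stats.py` — Shapiro-Wilk, split-plot RM-ANOVA (Mauchly +
  Greenhouse-Geisser), rank tests with bootstrap CIs
- `src/gripletrack/io.py`, `pipeline.py`, `cli.py` — file dialects, reproducible
  pipeline, command line
- `docs/methods.md` — model assumptions, calibration, numerical choices, limitations
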