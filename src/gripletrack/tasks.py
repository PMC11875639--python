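"""Design of the grip-force pursuit target lines and the trial protocol.

Each 23 s trial shows a target force trajectory sampled at 0.1 s
(230 samples): a 3 s preparation hold at 0.25 kg, a 10 s *random* half
(one of five different waveforms) and a 10 s *repeat* half that is
identical in every trial.  Both halves are truncated 6-harmonic Fourier
series with fundamental frequency ``omega = 2*pi/18`` rad/s, constrained
so the composed line stays within 0.06-0.4 kg and the two halves join
continuously in value and (approximately) in slope.

The numeric Fourier coefficients of the published task set are not
reproduced here; :func:`solve_coefficients` derives a fresh feasible set
from the published constraints, so any solved set is functionally
equivalent for the downstream scoring pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "N1",
    "N",
    "N_SAMPLES",
    "DELTA_T",
    "OMEGA",
    "HOLD_FORCE",
    "FORCE_LOW",
    "FORCE_HIGH",
    "COEFF_BOX",
    "COEFF_SCALE",
    "TargetLineCoefficients",
    "TaskSpec",
    "ProtocolSchedule",
    "ConstraintReport",
    "eval_random_line",
    "eval_repeat_line",
    "compose_task",
    "solve_coefficients",
    "build_task_set",
    "validate_task",
    "validate_task_set",
    "make_schedule",
]

#: preparation samples (3 s), tracked samples per half (10 s), sampling step
N1 = 30
N = 100
N_SAMPLES = N1 + 2 * N  # 230 samples = 23 s
DELTA_T = 0.1  # s
OMEGA = 2.0 * np.pi / 18.0  # rad/s, fundamental period 18 s
N_HARMONICS = 6

HOLD_FORCE = 0.25  # kg, constant level of the first 3 s
FORCE_LOW = 0.06  # kg, lower bound of the tracked waveform
FORCE_HIGH = 0.40  # kg, upper bound of the tracked waveform

#: admissible box for raw coefficients and the raw-to-kg scale factor
COEFF_BOX = 5.0
COEFF_SCALE = 0.1

#: default tolerance for the slope-matching boundary condition, kg per step
DEFAULT_SLOPE_TOL = 0.005

#: published first three blocks of the task-number sequence
PUBLISHED_SCHEDULE_PREFIX = ((4, 3, 1, 3, 4), (1, 2, 2, 4, 1), (5, 1, 5, 4, 4))


@dataclass(frozen=True)
class TargetLineCoefficients:
    """Fourier coefficients of one target line, in raw (display) units.

    ``force_kg = COEFF_SCALE * (b0 + sum_n a[n] sin(...) + b[n] cos(...))``.
    """

    role: Literal["random", "repeat"]
    task_id: int | None  # 1..5 for random lines, None for the repeat line
    b0: float
    a: tuple[float, ...]  # 6 sine amplitudes, harmonic n = 1..6
    b: tuple[float, ...]  # 6 cosine amplitudes
    scale: float = COEFF_SCALE

    def __post_init__(self) -> None:
        if self.role not in ("random", "repeat"):
            raise ValueError(f"unknown role {self.role!r}")
        if len(self.a) != N_HARMONICS or len(self.b) != N_HARMONICS:
            raise ValueError("exactly 6 sine and 6 cosine coefficients required")
        if self.role == "random" and self.task_id not in (1, 2, 3, 4, 5):
            raise ValueError("random lines carry task_id in 1..5")

    def in_box(self, box: float = COEFF_BOX) -> bool:
        vals = (self.b0, *self.a, *self.b)
        return all(abs(v) <= box for v in vals)

    def series(self, phase_s: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the Fourier series at phase ``phase_s`` seconds, in kg."""
        phase = np.asarray(phase_s, dtype=float)
        n = np.arange(1, N_HARMONICS + 1)
        ang = np.multiply.outer(phase, n * OMEGA)
        out = self.scale * (
            self.b0
            + (np.sin(ang) * np.asarray(self.a)).sum(axis=-1)
            + (np.cos(ang) * np.asarray(self.b)).sum(axis=-1)
        )
        return float(out) if np.isscalar(phase_s) else out


@dataclass(frozen=True)
class TaskSpec:
    """One composed 230-sample target trajectory f_d(k), k = 1..230."""

    task_id: int
    samples: np.ndarray  # force in kg, shape (230,)
    n1: int = N1
    n: int = N
    delta_t: float = DELTA_T
    omega: float = OMEGA

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.shape != (N_SAMPLES,):
            raise ValueError(f"expected {N_SAMPLES} samples, got {samples.shape}")

    @property
    def random_slice(self) -> slice:
        """0-based slice of the random half (k = N1+1 .. N1+N)."""
        return slice(N1, N1 + N)

    @property
    def repeat_slice(self) -> slice:
        """0-based slice of the repeat half (k = N1+N+1 .. N1+2N)."""
        return slice(N1 + N, N1 + 2 * N)

    @property
    def time_s(self) -> np.ndarray:
        return (np.arange(N_SAMPLES)) * self.delta_t


@dataclass(frozen=True)
class ProtocolSchedule:
    """10 blocks of 5 task ids each; identical for every participant."""

    blocks: tuple[tuple[int, ...], ...]
    rest_between_blocks_s: float = 30.0

    def __post_init__(self) -> None:
        if len(self.blocks) != 10 or any(len(b) != 5 for b in self.blocks):
            raise ValueError("schedule must be 10 blocks of 5 trials")
        if any(t not in (1, 2, 3, 4, 5) for b in self.blocks for t in b):
            raise ValueError("task ids must lie in 1..5")

    @property
    def trials(self) -> tuple[int, ...]:
        """Flat 50-trial task-id sequence."""
        return tuple(t for b in self.blocks for t in b)


def _check_role(coeffs: TargetLineCoefficients, role: str) -> None:
    if coeffs.role != role:
        raise ValueError(f"expected a {role} line, got {coeffs.role}")


def eval_random_line(
    coeffs: TargetLineCoefficients, k: int | np.ndarray
) -> float | np.ndarray:
    """Random-half target force at 1-based sample index k, phase (k-N1)*dT."""
    _check_role(coeffs, "random")
    phase = (np.asarray(k, dtype=float) - N1) * DELTA_T
    out = coeffs.series(phase)
    return float(out) if np.isscalar(k) else out


def eval_repeat_line(
    coeffs: TargetLineCoefficients, k: int | np.ndarray
) -> float | np.ndarray:
    """Repeat-half target force at 1-based sample index k, phase (k-N1-N)*dT."""
    _check_role(coeffs, "repeat")
    phase = (np.asarray(k, dtype=float) - N1 - N) * DELTA_T
    out = coeffs.series(phase)
    return float(out) if np.isscalar(k) else out


def compose_task(
    task_id: int,
    random_coeffs: TargetLineCoefficients,
    repeat_coeffs: TargetLineCoefficients,
    *,
    validate: bool = True,
    slope_tol: float = DEFAULT_SLOPE_TOL,
) -> TaskSpec:
    """Assemble the piecewise 230-sample trajectory for one task.

    Samples 1..N1 hold the random line's phase-0 value, N1+1..N1+N follow
    the random line, N1+N+1..N1+2N follow the repeat line.
    """
    _check_role(random_coeffs, "random")
    _check_role(repeat_coeffs, "repeat")
    if random_coeffs.task_id != task_id:
        raise ValueError(
            f"random line is for task {random_coeffs.task_id}, not {task_id}"
        )
    k = np.arange(1, N_SAMPLES + 1)
    samples = np.empty(N_SAMPLES)
    samples[:N1] = eval_random_line(random_coeffs, N1)
    samples[N1 : N1 + N] = eval_random_line(random_coeffs, k[N1 : N1 + N])
    samples[N1 + N :] = eval_repeat_line(repeat_coeffs, k[N1 + N :])
    spec = TaskSpec(task_id=task_id, samples=samples)
    if validate:
        report = validate_task(spec, slope_tol=slope_tol)
        if not report.passed:
            raise ValueError(
                "composed trajectory violates: "
                + ", ".join(c for c, ok, _ in report.constraints if not ok)
            )
    return spec


@dataclass
class ConstraintReport:
    """Per-constraint pass/fail with measured residuals (report-only)."""

    constraints: list[tuple[str, bool, float]] = field(default_factory=list)

    def add(self, name: str, passed: bool, residual: float) -> None:
        self.constraints.append((name, bool(passed), float(residual)))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.constraints)

    def residual(self, name: str) -> float:
        for c, _, r in self.constraints:
            if c == name:
                return r
        raise KeyError(name)


def validate_task(
    spec: TaskSpec,
    *,
    slope_tol: float = DEFAULT_SLOPE_TOL,
    atol: float = 1e-9,
) -> ConstraintReport:
    """Independent constraint checker for one composed trajectory."""
    f = spec.samples
    rep = ConstraintReport()
    rep.add("length_230", f.shape == (N_SAMPLES,), float(f.shape[0] - N_SAMPLES))

    hold_resid = float(np.max(np.abs(f[:N1] - HOLD_FORCE)))
    rep.add("hold_0.25kg_first_3s", hold_resid <= atol, hold_resid)

    tracked = f[N1:]
    range_resid = float(
        max(0.0, FORCE_LOW - tracked.min(), tracked.max() - FORCE_HIGH)
    )
    rep.add("range_0.06_0.40kg", range_resid <= atol, range_resid)

    # both junctions are exact in the function sense (the hold level is the
    # random line's phase-0 value; the boundary values of the two halves are
    # equal by construction), so the one-sample step across each junction can
    # only be a smooth waveform increment
    step_tol = 0.025  # kg, upper bound on a one-sample step of a smooth line
    junction1 = float(abs(f[N1 - 1] - f[N1]))  # prep hold -> random half
    rep.add("junction_prep_random_step", junction1 <= step_tol, junction1)
    junction2 = float(abs(f[N1 + N - 1] - f[N1 + N]))
    rep.add("junction_random_repeat_step", junction2 <= step_tol, junction2)

    slope_resid = float(
        abs((f[N1 + N - 2] - f[N1 + N - 1]) - (f[N1 + N - 1] - f[N1 + N]))
    )
    rep.add("slope_match", slope_resid <= slope_tol, slope_resid)
    return rep


def validate_task_set(
    specs: Sequence[TaskSpec], *, slope_tol: float = DEFAULT_SLOPE_TOL
) -> ConstraintReport:
    """Constraint report over the full five-task set (adds cross-task checks)."""
    rep = ConstraintReport()
    rep.add("five_tasks", len(specs) == 5, float(len(specs) - 5))
    for spec in specs:
        sub = validate_task(spec, slope_tol=slope_tol)
        for cname, ok, resid in sub.constraints:
            rep.add(f"task{spec.task_id}:{cname}", ok, resid)
    if len(specs) >= 2:
        ref = specs[0].samples[specs[0].repeat_slice]
        ident = all(
            np.array_equal(s.samples[s.repeat_slice], ref) for s in specs[1:]
        )
        rep.add("repeat_half_identical", ident, 0.0 if ident else 1.0)
    return rep


def _draw_harmonics(rng: np.random.Generator, amp: float) -> np.ndarray:
    """Raw harmonic amplitudes with a 1/n roll-off (smooth, trackable lines)."""
    n = np.arange(1, N_HARMONICS + 1)
    return rng.uniform(-amp, amp, N_HARMONICS) / n


def solve_coefficients(
    seed: int,
    *,
    slope_tol: float = DEFAULT_SLOPE_TOL,
    max_iter: int = 100_000,
) -> tuple[list[TargetLineCoefficients], TargetLineCoefficients]:
    """Derive a feasible coefficient set for the five random lines + repeat line.

    The two equality constraints (0.25 kg start value; value continuity at
    the random/repeat boundary) are solved linearly for b0 and b1 of each
    random line; the slope-match, range and box constraints are satisfied by
    seeded rejection sampling.  Deterministic given ``seed``.

    Returns ``(random_lines, repeat_line)``; raises ``RuntimeError`` with
    diagnostics if no feasible set is found within ``max_iter`` draws.
    """
    rng = np.random.default_rng(seed)
    k_all = np.arange(1, N_SAMPLES + 1)

    # -- repeat line: free except for range over its own half and the box
    repeat = None
    for _ in range(max_iter):
        a = _draw_harmonics(rng, 1.0)
        b = _draw_harmonics(rng, 1.0)
        start_kg = rng.uniform(0.14, 0.32)  # its value at phase 0
        b0 = start_kg / COEFF_SCALE - b.sum()
        cand = TargetLineCoefficients("repeat", None, float(b0), tuple(a), tuple(b))
        if not cand.in_box():
            continue
        vals = eval_repeat_line(cand, k_all[N1 + N :])
        if vals.min() >= FORCE_LOW + 0.005 and vals.max() <= FORCE_HIGH - 0.005:
            repeat = cand
            break
    if repeat is None:
        raise RuntimeError(
            f"no feasible repeat line in {max_iter} draws (seed={seed})"
        )
    c_rep = repeat.series(0.0)  # kg value both halves must share at the boundary
    rep_slope = repeat.series(0.0) - repeat.series(DELTA_T)  # f(130) - f(131)

    # -- random lines: b0, b1 solved from the two equality constraints
    phase_end = N * DELTA_T  # 10 s, phase of k = N1+N on the random line
    n_idx = np.arange(1, N_HARMONICS + 1)
    cos_end = np.cos(n_idx * OMEGA * phase_end)
    sin_end = np.sin(n_idx * OMEGA * phase_end)
    lhs = np.array([[1.0, 1.0], [1.0, cos_end[0]]])

    randoms: list[TargetLineCoefficients] = []
    attempts = 0
    for task_id in range(1, 6):
        found = None
        while attempts < max_iter:
            attempts += 1
            a = _draw_harmonics(rng, 1.0)
            b = _draw_harmonics(rng, 1.0)
            # unknowns: b0 and b1; a1..a6, b2..b6 as drawn
            rhs = np.array(
                [
                    HOLD_FORCE / COEFF_SCALE - b[1:].sum(),
                    c_rep / COEFF_SCALE - (a * sin_end).sum() - (b[1:] * cos_end[1:]).sum(),
                ]
            )
            b0, b1 = np.linalg.solve(lhs, rhs)
            b = b.copy()
            b[0] = b1
            cand = TargetLineCoefficients(
                "random", task_id, float(b0), tuple(a), tuple(b)
            )
            if not cand.in_box():
                continue
            vals = eval_random_line(cand, k_all[N1 : N1 + N])
            # small margin keeps the line feasible after 4-decimal file rounding
            if vals.min() < FORCE_LOW + 0.002 or vals.max() > FORCE_HIGH - 0.002:
                continue
            ran_slope = float(vals[-2] - vals[-1])  # f(129) - f(130)
            if abs(ran_slope - rep_slope) > slope_tol:
                continue
            found = cand
            break
        if found is None:
            raise RuntimeError(
                f"no feasible random line {task_id} within {max_iter} total draws "
                f"(seed={seed}, slope_tol={slope_tol})"
            )
        randoms.append(found)
    return randoms, repeat


def build_task_set(
    seed: int, *, slope_tol: float = DEFAULT_SLOPE_TOL
) -> list[TaskSpec]:
    """Solve coefficients and compose the five validated TaskSpecs."""
    randoms, repeat = solve_coefficients(seed, slope_tol=slope_tol)
    return [
        compose_task(c.task_id, c, repeat, slope_tol=slope_tol) for c in randoms
    ]


def make_schedule(seed: int, use_published_prefix: bool = True) -> ProtocolSchedule:
    """Build the 10-block x 5-trial task-number schedule.

    With ``use_published_prefix`` the first three blocks are the published
    sequence 4-3-1-3-4, 1-2-2-4-1, 5-1-5-4-4; remaining blocks are seeded
    uniform draws over tasks 1..5.
    """
    rng = np.random.default_rng(seed)
    blocks: list[tuple[int, ...]] = []
    if use_published_prefix:
        blocks.extend(PUBLISHED_SCHEDULE_PREFIX)
    while len(blocks) < 10:
        blocks.append(tuple(int(t) for t in rng.integers(1, 6, 5)))
    return ProtocolSchedule(blocks=tuple(blocks))
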