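"""CSV/JSON dialects for tasks, trials, scores and analysis reports.

All files are UTF-8 comma-separated with a mandatory header row and '.'
decimals.  Forces are written with 4 decimals (kg) and learning rates
with 1 decimal (%), the reporting precision of the scores; rounding is
applied only at the file boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import BlockScore, LearningRates, TrialRecord, TrialScore
from .tasks import N_SAMPLES, TargetLineCoefficients, TaskSpec

__all__ = [
    "write_coefficients",
    "read_coefficients",
    "write_tasks",
    "read_tasks",
    "write_trials",
    "read_trials",
    "write_scores",
    "read_scores",
    "write_report",
    "read_report",
]

_COEF_COLS = (
    ["role", "task_id", "b0"]
    + [f"a{n}" for n in range(1, 7)]
    + [f"b{n}" for n in range(1, 7)]
    + ["scale_factor"]
)


def write_coefficients(
    path: str | Path,
    randoms: Sequence[TargetLineCoefficients],
    repeat: TargetLineCoefficients,
    *,
    solver_seed: int | None = None,
) -> None:
    """One row per target line; a header comment records the solver seed."""
    rows = []
    for c in (*randoms, repeat):
        rows.append(
            [c.role, c.task_id if c.task_id is not None else "", c.b0]
            + list(c.a)
            + list(c.b)
            + [c.scale]
        )
    df = pd.DataFrame(rows, columns=_COEF_COLS)
    with open(path, "w", encoding="utf-8") as fh:
        if solver_seed is not None:
            fh.write(f"# solver_seed={solver_seed}\n")
        # default (shortest round-trip) float formatting: coefficient files
        # are the canonical solver output and must survive a read unchanged
        df.to_csv(fh, index=False)


def read_coefficients(
    path: str | Path,
) -> tuple[list[TargetLineCoefficients], TargetLineCoefficients]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(_COEF_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"coefficient file missing columns: {sorted(missing)}")
    randoms, repeat = [], None
    for i, row in df.iterrows():
        coeffs = TargetLineCoefficients(
            role=row["role"],
            task_id=int(row["task_id"]) if row["role"] == "random" else None,
            b0=float(row["b0"]),
            a=tuple(float(row[f"a{n}"]) for n in range(1, 7)),
            b=tuple(float(row[f"b{n}"]) for n in range(1, 7)),
            scale=float(row["scale_factor"]),
        )
        if coeffs.role == "random":
            randoms.append(coeffs)
        elif repeat is None:
            repeat = coeffs
        else:
            raise ValueError(f"row {i}: more than one repeat line")
    if len(randoms) != 5 or repeat is None:
        raise ValueError("expected 5 random lines and 1 repeat line")
    return randoms, repeat


def write_tasks(path: str | Path, specs: Sequence[TaskSpec]) -> None:
    """Long CSV: task_id, k (1-based), t_seconds, force_kg (4 decimals)."""
    frames = []
    for s in specs:
        frames.append(
            pd.DataFrame(
                {
                    "task_id": s.task_id,
                    "k": np.arange(1, N_SAMPLES + 1),
                    "t_seconds": np.round(np.arange(N_SAMPLES) * s.delta_t, 1),
                    "force_kg": s.samples,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.4f")


def read_tasks(path: str | Path) -> list[TaskSpec]:
    df = pd.read_csv(path)
    required = {"task_id", "k", "force_kg"}
    if not required <= set(df.columns):
        raise ValueError(f"task file must carry columns {sorted(required)}")
    specs = []
    for task_id, grp in df.groupby("task_id", sort=True):
        grp = grp.sort_values("k")
        if list(grp["k"]) != list(range(1, N_SAMPLES + 1)):
            raise ValueError(f"task {task_id}: k must be exactly 1..{N_SAMPLES}")
        specs.append(TaskSpec(task_id=int(task_id), samples=grp["force_kg"].to_numpy()))
    return specs


def write_trials(path: str | Path, trials: Sequence[TrialRecord]) -> None:
    """Long CSV: participant_id, group, trial_index, task_id, k, force_kg."""
    frames = []
    for t in trials:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": t.participant_id,
                    "group": t.group,
                    "trial_index": t.trial_index,
                    "task_id": t.task_id,
                    "k": np.arange(1, N_SAMPLES + 1),
                    "force_kg": t.measured,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.4f")


def read_trials(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    required = {"participant_id", "group", "trial_index", "task_id", "k", "force_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    out = []
    for (pid, trial_index), grp in df.groupby(
        ["participant_id", "trial_index"], sort=True
    ):
        grp = grp.sort_values("k")
        if list(grp["k"]) != list(range(1, N_SAMPLES + 1)):
            raise ValueError(
                f"participant {pid} trial {trial_index}: "
                f"k must be exactly 1..{N_SAMPLES}"
            )
        out.append(
            TrialRecord(
                participant_id=str(pid),
                group=str(grp["group"].iloc[0]),
                trial_index=int(trial_index),
                task_id=int(grp["task_id"].iloc[0]),
                measured=grp["force_kg"].to_numpy(),
            )
        )
    return out


def write_scores(
    directory: str | Path,
    per_participant: dict[str, tuple[str, list[TrialScore], list[BlockScore], LearningRates]],
) -> None:
    """Write trials.csv / blocks.csv / learning_rates.csv under ``directory``.

    ``per_participant`` maps participant_id to (group, scores, blocks, rates).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trial_rows, block_rows, lr_rows = [], [], []
    for pid, (group, scores, blocks, rates) in per_participant.items():
        for s in scores:
            trial_rows.append((pid, group, s.trial_index, s.task_id, s.agf_ran, s.agf_rep))
        for b in blocks:
            block_rows.append((pid, group, b.block_index, b.mean_agf_ran, b.mean_agf_rep))
        lr_rows.append((pid, group, rates.lr_ran, rates.lr_rep))
    pd.DataFrame(
        trial_rows,
        columns=["participant_id", "group", "trial_index", "task_id", "agf_ran_kg", "agf_rep_kg"],
    ).to_csv(directory / "trial_scores.csv", index=False, float_format="%.4f")
    pd.DataFrame(
        block_rows,
        columns=["participant_id", "group", "block_index", "mean_agf_ran_kg", "mean_agf_rep_kg"],
    ).to_csv(directory / "block_scores.csv", index=False, float_format="%.4f")
    pd.DataFrame(
        lr_rows, columns=["participant_id", "group", "lr_ran_pct", "lr_rep_pct"]
    ).to_csv(directory / "learning_rates.csv", index=False, float_format="%.1f")


def read_scores(directory: str | Path) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    out = {}
    for name in ("trial_scores", "block_scores", "learning_rates"):
        f = directory / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f)
        out[name] = pd.read_csv(f)
    return out


def write_report(path: str | Path, report: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
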