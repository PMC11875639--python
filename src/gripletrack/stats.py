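"""Group-comparison statistics for scored cohorts.

Implements the analysis plan applied to the block-wise mean AGF scores
and learning rates: Shapiro-Wilk normality screening, a two-within
(block x task) by one-between (group) split-plot repeated-measures ANOVA
with Mauchly's sphericity test and the Greenhouse-Geisser correction,
and nonparametric learning-rate comparisons (Mann-Whitney between
groups, Wilcoxon signed-rank within group) with seeded bootstrap
percentile intervals for the mean difference.

The split-plot engine uses the classical stratum decomposition for a
design that is balanced within subjects (every subject contributes all
block x task cells) but may have unequal group sizes; sums of squares
within each stratum are Type III (computed by model comparison with
sum-to-zero contrasts), which matches the conventions of mainstream
statistics packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityResult",
    "ComparisonResult",
    "DegenerateDataError",
    "normality_check",
    "rm_anova",
    "compare_between",
    "compare_within",
    "run_full_analysis",
]

ALPHA = 0.05
N_BOOT = 10_000


class DegenerateDataError(ValueError):
    """Raised for inputs on which the requested test is undefined."""


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    """Rank-test outcome with a bootstrap interval for the mean difference."""

    test: str  # "mann-whitney" | "wilcoxon"
    statistic: float
    p_value: float
    ci_low: float  # 95% percentile bootstrap CI of the mean difference
    ci_high: float
    mean_difference: float
    n1: int
    n2: int

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "ci95": [self.ci_low, self.ci_high],
            "mean_difference": self.mean_difference,
            "n": [self.n1, self.n2],
        }


def normality_check(values) -> NormalityResult:
    """Shapiro-Wilk test of a single variable (report-only screening)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateDataError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input: normality test undefined")
    stat, p = sps.shapiro(x)
    return NormalityResult(statistic=float(stat), p_value=float(p), n=int(x.size))


# ---------------------------------------------------------------------------
# split-plot RM-ANOVA: within = block (10) x task (2), between = group
# ---------------------------------------------------------------------------


def _effect_code(labels: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding, shape (n, levels-1)."""
    levels = list(dict.fromkeys(labels.tolist()))
    k = len(levels)
    out = np.zeros((labels.size, k - 1))
    for j, lev in enumerate(levels[:-1]):
        out[labels == lev, j] = 1.0
    out[labels == levels[-1], :] = -1.0
    return out


def _type3_ss(y: np.ndarray, blocks_of_cols: list[np.ndarray]) -> tuple[list[float], float]:
    """Type-III SS per predictor block by full-vs-reduced model comparison."""
    X_full = np.column_stack(blocks_of_cols)
    rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
    ss = []
    for i in range(len(blocks_of_cols)):
        X_red = np.column_stack(
            [b for j, b in enumerate(blocks_of_cols) if j != i]
        ) if len(blocks_of_cols) > 1 else np.zeros((y.size, 0))
        if X_red.shape[1]:
            beta = np.linalg.lstsq(X_red, y, rcond=None)[0]
            rss_red = float(np.sum((y - X_red @ beta) ** 2))
        else:
            rss_red = float(np.sum(y**2))
        ss.append(rss_red - rss_full)
    return ss, rss_full


def _safe_f(ss_effect: float, df_effect: int, ss_err: float, df_err: int) -> float:
    """F ratio, nan for empty effects or a zero-variance error stratum."""
    if df_effect <= 0 or df_err <= 0 or ss_err <= 0:
        return float("nan")
    return (ss_effect / df_effect) / (ss_err / df_err)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the difference space."""
    c = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(c[:, : k - 1])
    return q.T  # rows orthonormal, each orthogonal to the unit vector


def _gg_epsilon(cov: np.ndarray, contrasts: np.ndarray) -> float:
    s = contrasts @ cov @ contrasts.T
    d = s.shape[0]
    tr = np.trace(s)
    denom = d * np.sum(s * s)
    if denom <= 0:  # no within-subject variability at all
        return 1.0
    eps = tr**2 / denom
    return float(min(1.0, max(eps, 1.0 / d)))


def _mauchly(cov: np.ndarray, contrasts: np.ndarray, df_cov: int) -> tuple[float, float]:
    """Mauchly's W and its chi-square p-value for one within effect."""
    s = contrasts @ cov @ contrasts.T
    d = s.shape[0]
    if d < 2:
        return 1.0, 1.0
    eigvals = np.linalg.eigvalsh(s)
    if np.any(eigvals <= 0):
        return 0.0, 0.0
    w = float(np.exp(np.sum(np.log(eigvals)) - d * np.log(np.mean(eigvals))))
    # chi-square approximation with the standard second-order correction
    rho = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * df_cov)
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * d + 2)
        / (288.0 * d**2 * df_cov**2 * rho**2)
    )
    z = -df_cov * rho * np.log(w)
    df = d * (d + 1) // 2 - 1
    p = sps.chi2.sf(z, df) + w2 * (sps.chi2.sf(z, df + 4) - sps.chi2.sf(z, df))
    return w, float(min(max(p, 0.0), 1.0))


def rm_anova(table: pd.DataFrame, value_col: str = "mean_agf") -> pd.DataFrame:
    """Split-plot ANOVA of block-wise mean AGF.

    ``table`` is a long DataFrame with columns ``participant``, ``group``,
    ``block`` (1..10), ``task`` ("random"/"repeat") and the value column;
    every participant must contribute exactly one value per block x task
    cell.  Returns one row per effect with uncorrected and
    Greenhouse-Geisser-corrected p-values and Mauchly's test for each
    within-subject effect.
    """
    required = {"participant", "group", "block", "task", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    wide = table.pivot_table(
        index=["participant", "group"],
        columns=["block", "task"],
        values=value_col,
        aggfunc="first",
        sort=True,
    )
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every block x task cell is required")
    b = table["block"].nunique()
    t = table["task"].nunique()
    if wide.shape[1] != b * t:
        raise ValueError("duplicated cells in the design table")
    groups = np.asarray([g for _, g in wide.index])
    y = wide.to_numpy().reshape(-1, b, t)  # (subjects, block, task)
    n_subj = y.shape[0]
    a = len(np.unique(groups))
    if n_subj <= a:
        raise ValueError("need more subjects than groups")

    g_codes = _effect_code(groups)  # (n, a-1)
    rows = []

    # --- between stratum: subject means (Type III: intercept retained so the
    # group hypothesis is on unweighted group means)
    m = y.mean(axis=(1, 2))
    intercept = np.ones((n_subj, 1))
    ss_list, rss = _type3_ss(m, [intercept, g_codes])
    ss_g = ss_list[1] * b * t
    ss_subj = rss * b * t
    df_g, df_s = a - 1, n_subj - a
    f_g = _safe_f(ss_g, df_g, ss_subj, df_s)
    rows.append(
        dict(effect="group", ss=ss_g, df1=df_g, df2=df_s, F=f_g,
             p_unc=float(sps.f.sf(f_g, df_g, df_s)) if np.isfinite(f_g) else np.nan,
             eps_gg=np.nan, p_gg=np.nan, mauchly_w=np.nan, mauchly_p=np.nan)
    )

    # pooled within-group covariance of the 20 cells
    flat = y.reshape(n_subj, b * t)
    resid = flat.copy()
    for g in np.unique(groups):
        sel = groups == g
        resid[sel] -= flat[sel].mean(axis=0)
    cov = resid.T @ resid / (n_subj - a)

    c_b = _orthonormal_contrasts(b)
    c_t = _orthonormal_contrasts(t)
    ones_b = np.full((1, b), 1.0 / np.sqrt(b))
    ones_t = np.full((1, t), 1.0 / np.sqrt(t))

    def within_stratum(name, z, k_eff, contrasts, scale):
        """One within stratum: effect + effect x group + residual error."""
        n_rows = z.shape[0] * z.shape[1]
        lev = np.tile(np.arange(z.shape[1]), z.shape[0])
        subj_g = np.repeat(g_codes, z.shape[1], axis=0)
        lcode = _effect_code(lev)
        inter = np.einsum("ij,ik->ijk", lcode, subj_g).reshape(n_rows, -1)
        blocks = [lcode, inter] if inter.shape[1] else [lcode]
        ss, rss_w = _type3_ss(z.reshape(n_rows), blocks)
        if not inter.shape[1]:
            ss = [ss[0], 0.0]
        df_e = k_eff
        df_i = k_eff * (a - 1)
        df_err = (n_subj - a) * k_eff
        eps = _gg_epsilon(cov, contrasts)
        w, w_p = _mauchly(cov, contrasts, n_subj - a)
        for nm, ssx, dfx in ((name, ss[0] * scale, df_e),
                             (f"{name}*group", ss[1] * scale, df_i)):
            f = _safe_f(ssx, dfx, rss_w * scale, df_err)
            rows.append(
                dict(effect=nm, ss=ssx, df1=dfx, df2=df_err, F=f,
                     p_unc=float(sps.f.sf(f, dfx, df_err)) if np.isfinite(f) else np.nan,
                     eps_gg=eps,
                     p_gg=float(sps.f.sf(f, dfx * eps, df_err * eps))
                     if np.isfinite(f) else np.nan,
                     mauchly_w=w, mauchly_p=w_p)
            )

    # block stratum: task-averaged, subject-centred
    zb = y.mean(axis=2) - m[:, None]
    within_stratum("block", zb, b - 1, np.kron(c_b, ones_t), scale=t)
    # task stratum
    zt = y.mean(axis=1) - m[:, None]
    within_stratum("task", zt, t - 1, np.kron(ones_b, c_t), scale=b)
    # block x task stratum: double-centred per subject
    zbt = y - y.mean(axis=2, keepdims=True) - y.mean(axis=1, keepdims=True) + m[:, None, None]
    zbt2 = zbt.reshape(n_subj, b * t)
    within_stratum("block*task", zbt2, (b - 1) * (t - 1), np.kron(c_b, c_t), scale=1)

    order = ["group", "block", "block*group", "task", "task*group",
             "block*task", "block*task*group"]
    return (
        pd.DataFrame(rows)
        .set_index("effect")
        .loc[order]
        .reset_index()
    )


# ---------------------------------------------------------------------------
# rank tests with bootstrap intervals
# ---------------------------------------------------------------------------


def _bootstrap_ci(
    stat_fn, draw_fn, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    boot = np.array([stat_fn(*draw_fn(rng)) for _ in range(n_boot)])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(lo), float(hi)


def _rank_method(n_max: int, has_ties: bool) -> str:
    return "exact" if (n_max <= 25 and not has_ties) else "asymptotic"


def compare_between(
    group1, group2, *, n_boot: int = N_BOOT, seed: int = 0
) -> ComparisonResult:
    """Two-sided Mann-Whitney U with a bootstrap CI for mean(g2) - mean(g1).

    Exact enumeration is used for small untied samples; otherwise the
    normal approximation with average ranks and continuity correction.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all observations tied: ranks are degenerate")
    ties = np.unique(pooled).size < pooled.size
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method=_rank_method(max(x.size, y.size), ties),
    )
    rng = np.random.default_rng(seed)
    lo, hi = _bootstrap_ci(
        lambda a, b: b.mean() - a.mean(),
        lambda r: (r.choice(x, x.size), r.choice(y, y.size)),
        n_boot,
        rng,
    )
    return ComparisonResult(
        test="mann-whitney", statistic=float(res.statistic),
        p_value=float(res.pvalue), ci_low=lo, ci_high=hi,
        mean_difference=float(y.mean() - x.mean()), n1=int(x.size), n2=int(y.size),
    )


def compare_within(
    values1, values2, *, n_boot: int = N_BOOT, seed: int = 0
) -> ComparisonResult:
    """Wilcoxon signed-rank on paired values with a CI for the mean difference.

    The difference (and its CI) is ``values2 - values1`` averaged over
    participants.  Raises for all-zero differences.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    ties = np.unique(np.abs(d[d != 0])).size < np.count_nonzero(d)
    method = "exact" if (d.size <= 25 and not ties and np.all(d != 0)) else "approx"
    res = sps.wilcoxon(x, y, alternative="two-sided", method=method, correction=True)
    rng = np.random.default_rng(seed)
    lo, hi = _bootstrap_ci(
        lambda dd: dd.mean(),
        lambda r: (r.choice(d, d.size),),
        n_boot,
        rng,
    )
    return ComparisonResult(
        test="wilcoxon", statistic=float(res.statistic), p_value=float(res.pvalue),
        ci_low=lo, ci_high=hi, mean_difference=float(d.mean()),
        n1=int(d.size), n2=int(d.size),
    )


def run_full_analysis(
    lr_nc: pd.DataFrame,
    lr_mci: pd.DataFrame,
    anova_table: pd.DataFrame | None = None,
    *,
    seed: int = 0,
    n_boot: int = N_BOOT,
) -> dict:
    """Full analysis plan on scored cohorts; returns a JSON-able report.

    ``lr_nc``/``lr_mci`` carry one row per participant with columns
    ``lr_ran`` and ``lr_rep`` (percent).  ``anova_table`` is the optional
    long block-means table for :func:`rm_anova`.
    """
    report: dict = {"alpha": ALPHA, "seed": seed}
    report["normality"] = {
        f"{grp}_{var}": vars(normality_check(df[var]))
        for grp, df in (("nc", lr_nc), ("mci", lr_mci))
        for var in ("lr_ran", "lr_rep")
    }
    report["between_group"] = {
        var: compare_between(
            lr_nc[var], lr_mci[var], seed=seed, n_boot=n_boot
        ).as_dict()
        for var in ("lr_ran", "lr_rep")
    }
    report["within_group"] = {
        grp: compare_within(
            df["lr_ran"], df["lr_rep"], seed=seed, n_boot=n_boot
        ).as_dict()
        for grp, df in (("nc", lr_nc), ("mci", lr_mci))
    }
    if anova_table is not None:
        report["rm_anova"] = rm_anova(anova_table).to_dict(orient="records")
    return report
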