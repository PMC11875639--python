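"""Statistical engine: rank tests vs enumeration, split-plot ANOVA vs
independent references, normality screening."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gripletrack.stats import (
    DegenerateDataError,
    compare_between,
    compare_within,
    normality_check,
    rm_anova,
    run_full_analysis,
)


# ---------------------------------------------------------------------------
# normality screening
# ---------------------------------------------------------------------------


class TestNormality:
    def test_gaussian_samples_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=50)
            if normality_check(x).p_value > 0.05:
                hits += 1
        assert hits >= 90

    def test_exponential_samples_usually_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=50)
            if normality_check(x).p_value < 0.05:
                hits += 1
        assert hits >= 80

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            normality_check([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(DegenerateDataError):
            normality_check([1.0, 2.0])


# ---------------------------------------------------------------------------
# rank tests vs exhaustive enumeration
# ---------------------------------------------------------------------------


def enumerate_mannwhitney_p(x, y):
    """Two-sided exact p by enumerating all pooled rank assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    centre = n1 * len(y) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = np.sum(ranks[list(combo)]) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            count += 1
    return count / total


def enumerate_wilcoxon_p(diffs):
    """Two-sided exact p over all sign assignments of the ranked |diffs|."""
    d = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    t_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = total = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        s = np.asarray(signs)
        t = min(ranks[s > 0].sum(), ranks[s < 0].sum())
        total += 1
        if t <= t_obs + 1e-12:
            count += 1
    return count / total


class TestRankTests:
    def test_toy_mannwhitney_exact(self):
        res = compare_between([1, 2, 3], [4, 5, 6], seed=0, n_boot=200)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(enumerate_mannwhitney_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", range(6))
    def test_mannwhitney_matches_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 8))
        y = rng.normal(size=rng.integers(3, 8))
        res = compare_between(x, y, seed=0, n_boot=100)
        assert res.p_value == pytest.approx(enumerate_mannwhitney_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_wilcoxon_matches_enumeration_small_n(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=6)
        b = a + rng.normal(0.4, 1.0, size=6)
        res = compare_within(a, b, seed=0, n_boot=100)
        assert res.p_value == pytest.approx(enumerate_wilcoxon_p(b - a), abs=1e-12)

    def test_wilcoxon_statistic_equals_hand_ranks(self):
        a = np.zeros(5)
        b = np.array([1.0, -2.0, 3.0, -4.0, 5.0])  # |d| ranks 1..5
        res = compare_within(a, b, seed=0, n_boot=100)
        assert res.statistic == min(1 + 3 + 5, 2 + 4)

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_between(x, x, seed=0, n_boot=500)
        assert res.p_value == pytest.approx(1.0, abs=0.01)
        assert res.ci_low <= 0.0 <= res.ci_high
        with pytest.raises(DegenerateDataError):
            compare_within(x, x)

    def test_all_tied_between_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_between([2.0, 2.0], [2.0, 2.0])

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        y = rng.normal(1.5, 1, 60)
        res = compare_between(x, y, seed=0, n_boot=1000)
        assert res.p_value < 0.01
        assert res.ci_low > 0.5  # CI of mean(y) - mean(x) excludes zero

    def test_bootstrap_ci_is_seeded(self):
        x = np.arange(10.0)
        y = x + 1.3
        a = compare_between(x, y, seed=5)
        b = compare_between(x, y, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


# ---------------------------------------------------------------------------
# split-plot RM-ANOVA
# ---------------------------------------------------------------------------


def anova_fixture() -> pd.DataFrame:
    """Small unbalanced-group design with a seeded generative structure."""
    rng = np.random.default_rng(42)
    rows = []
    for g, n in (("A", 6), ("B", 5)):
        for s in range(n):
            subj_eff = rng.normal(0, 0.5)
            for bi in range(1, 5):
                for ti, task in enumerate(["random", "repeat"]):
                    mu = 1.0 + 0.2 * bi * (ti + 1) * (1.5 if g == "B" else 1.0) + subj_eff
                    rows.append(
                        dict(participant=f"{g}{s}", group=g, block=bi, task=task,
                             mean_agf=round(mu + rng.normal(0, 0.3), 6))
                    )
    return pd.DataFrame(rows)


# expected values computed once with R 4.3.3 car::Anova(lm(resp ~ group),
# idesign = ~block*task, type = 3) under sum-to-zero contrasts on the same
# fixture (see docs/methods.md for the validation protocol)
R_CAR_EXPECTED = {
    #                 F          p_unc        eps_gg      p_gg
    "group":            (0.8171,    0.389586,    None,      None),
    "block":            (83.2763,   9.168e-14,   0.6518925, 1.195860e-09),
    "block*group":      (5.1231,    0.006191,    0.6518925, 1.815145e-02),
    "task":             (169.2666,  3.857e-07,   None,      3.857e-07),
    "task*group":       (6.0117,    0.036644,    None,      0.036644),
    "block*task":       (12.2329,   3.076e-05,   0.6095386, 7.008822e-04),
    "block*task*group": (0.7756,    0.517814,    0.6095386, 4.657645e-01),
}
R_CAR_MAUCHLY = {"block": (0.40257, 0.22229), "block*task": (0.39365, 0.20979)}


class TestRmAnova:
    def test_matches_r_car_type3_oracle(self):
        res = rm_anova(anova_fixture()).set_index("effect")
        for effect, (f, p, eps, p_gg) in R_CAR_EXPECTED.items():
            row = res.loc[effect]
            assert row["F"] == pytest.approx(f, rel=1e-4), effect
            assert row["p_unc"] == pytest.approx(p, rel=1e-3), effect
            if eps is not None:
                assert row["eps_gg"] == pytest.approx(eps, rel=1e-5), effect
            if p_gg is not None:
                assert row["p_gg"] == pytest.approx(p_gg, rel=1e-3), effect
        for effect, (w, p) in R_CAR_MAUCHLY.items():
            assert res.loc[effect, "mauchly_w"] == pytest.approx(w, rel=1e-4)
            # R's mauchly.test uses a slightly different second-order term
            assert res.loc[effect, "mauchly_p"] == pytest.approx(p, abs=5e-3)

    def test_matches_statsmodels_within_only_design(self):
        from statsmodels.stats.anova import AnovaRM

        df = anova_fixture()
        df = df[df.group == "A"].copy()
        res = rm_anova(df).set_index("effect")
        sm = AnovaRM(df, depvar="mean_agf", subject="participant",
                     within=["block", "task"]).fit().anova_table
        for ours, theirs in (("block", "block"), ("task", "task"),
                             ("block*task", "block:task")):
            assert res.loc[ours, "F"] == pytest.approx(
                sm.loc[theirs, "F Value"], rel=1e-8
            )
            assert res.loc[ours, "p_unc"] == pytest.approx(
                sm.loc[theirs, "Pr > F"], rel=1e-8
            )

    def test_constant_data_yields_no_significant_effects(self):
        df = anova_fixture()
        df["mean_agf"] = 0.123
        res = rm_anova(df)
        assert not np.any(res["p_unc"].to_numpy() < 0.05)

    def test_compound_symmetric_data_has_epsilon_near_one(self):
        rng = np.random.default_rng(3)
        rows = []
        for g, n in (("A", 20), ("B", 20)):
            for s in range(n):
                subj = rng.normal(0, 1.0)
                for bi in range(1, 5):
                    for task in ("random", "repeat"):
                        rows.append(dict(participant=f"{g}{s}", group=g, block=bi,
                                         task=task,
                                         mean_agf=subj + rng.normal(0, 0.5)))
        res = rm_anova(pd.DataFrame(rows)).set_index("effect")
        assert res.loc["block", "eps_gg"] > 0.8
        assert res.loc["block", "mauchly_p"] > 0.05

    @pytest.mark.parametrize("seed", range(4))
    def test_gg_correction_is_conservative_near_significance(self, seed):
        # shrinking both dfs by epsilon <= 1 raises the p of any F large
        # enough to approach significance; for small F the correction can
        # move either way (R car / SPSS behave identically), but those
        # effects are far from any decision boundary
        rng = np.random.default_rng(seed)
        df = anova_fixture().copy()
        df["mean_agf"] = rng.normal(size=len(df))
        res = rm_anova(df)
        within = res[(res.effect != "group") & (res.p_unc < 0.10)]
        assert np.all(within["p_gg"].to_numpy() >= within["p_unc"].to_numpy() - 1e-12)

    def test_unbalanced_cells_rejected(self):
        df = anova_fixture().iloc[:-1]
        with pytest.raises(ValueError, match="balanced|cell"):
            rm_anova(df)


class TestFullAnalysis:
    def test_report_complete_and_deterministic(self, nc_cohort_lr, mci_cohort_lr):
        lr_nc = pd.DataFrame({"lr_ran": nc_cohort_lr["lr_ran"],
                              "lr_rep": nc_cohort_lr["lr_rep"]})
        lr_mci = pd.DataFrame({"lr_ran": mci_cohort_lr["lr_ran"],
                               "lr_rep": mci_cohort_lr["lr_rep"]})
        rep1 = run_full_analysis(lr_nc, lr_mci, seed=3, n_boot=500)
        rep2 = run_full_analysis(lr_nc, lr_mci, seed=3, n_boot=500)
        assert rep1 == rep2
        assert set(rep1["between_group"]) == {"lr_ran", "lr_rep"}
        assert set(rep1["within_group"]) == {"nc", "mci"}
        assert set(rep1["normality"]) == {
            "nc_lr_ran", "nc_lr_rep", "mci_lr_ran", "mci_lr_rep"
        }
        for cmp in rep1["between_group"].values():
            assert 0.0 <= cmp["p_value"] <= 1.0
            assert cmp["ci95"][0] <= cmp["ci95"][1]
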