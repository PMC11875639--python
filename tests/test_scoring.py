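"""AGF scores, block means and learning rates against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gripletrack.scoring import (
    BlockScore,
    TrialRecord,
    TrialScore,
    UndefinedLearningRateError,
    agf_random,
    agf_repeat,
    block_means,
    learning_rates,
    score_participant,
)
from gripletrack.tasks import N, N1


def make_trial(spec, measured, trial_index=1, **kw):
    return TrialRecord(
        participant_id=kw.get("pid", "p1"),
        group=kw.get("group", "NC"),
        trial_index=trial_index,
        task_id=spec.task_id,
        measured=measured,
    )


class TestAgf:
    def test_perfect_tracking_scores_zero(self, task_set):
        spec = task_set[0]
        t = make_trial(spec, spec.samples.copy())
        assert agf_random(t, spec) == 0.0
        assert agf_repeat(t, spec) == 0.0

    def test_constant_offset_recovered_exactly(self, task_set):
        spec = task_set[1]
        t = make_trial(spec, spec.samples + 0.05)
        assert agf_random(t, spec) == pytest.approx(0.05, abs=1e-12)
        t2 = make_trial(spec, np.clip(spec.samples - 0.02, 0, None))
        assert agf_repeat(t2, spec) == pytest.approx(0.02, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_loop(self, task_set, seed):
        rng = np.random.default_rng(seed)
        spec = task_set[seed % 5]
        measured = np.clip(spec.samples + rng.normal(0, 0.02, 230), 0.0, 0.5)
        t = make_trial(spec, measured)
        total_ran = sum(
            abs(spec.samples[k - 1] - measured[k - 1]) for k in range(N1 + 1, N1 + N + 1)
        )
        total_rep = sum(
            abs(spec.samples[k - 1] - measured[k - 1])
            for k in range(N1 + N + 1, N1 + 2 * N + 1)
        )
        assert agf_random(t, spec) == pytest.approx(total_ran / N, abs=1e-12)
        assert agf_repeat(t, spec) == pytest.approx(total_rep / N, abs=1e-12)

    def test_preparation_samples_never_affect_scores(self, task_set, rng):
        spec = task_set[2]
        measured = np.clip(spec.samples + rng.normal(0, 0.01, 230), 0.0, 0.5)
        base = make_trial(spec, measured)
        perturbed = measured.copy()
        perturbed[:N1] = rng.uniform(0.0, 0.5, N1)
        pert = make_trial(spec, perturbed)
        assert agf_random(pert, spec) == agf_random(base, spec)
        assert agf_repeat(pert, spec) == agf_repeat(base, spec)

    def test_residual_scale_equivariance(self, task_set):
        spec = task_set[3]
        resid = 0.01 * np.sin(np.linspace(0, 7, 230))
        lam = 2.5
        t1 = make_trial(spec, spec.samples + resid)
        t2 = make_trial(spec, spec.samples + lam * resid)
        assert agf_random(t2, spec) == pytest.approx(lam * agf_random(t1, spec))
        assert agf_repeat(t2, spec) == pytest.approx(lam * agf_repeat(t1, spec))

    def test_task_mismatch_rejected(self, task_set):
        t = make_trial(task_set[0], task_set[0].samples.copy())
        with pytest.raises(ValueError, match="task"):
            agf_random(t, task_set[1])


class TestTrialRecordContracts:
    def test_out_of_range_force_rejected(self, task_set):
        bad = task_set[0].samples.copy()
        bad[50] = 0.6
        with pytest.raises(ValueError, match="device range"):
            make_trial(task_set[0], bad)

    def test_missing_samples_rejected(self, task_set):
        bad = task_set[0].samples.copy()
        bad[10] = np.nan
        with pytest.raises(ValueError, match="missing"):
            make_trial(task_set[0], bad)

    def test_block_index_derivation(self, task_set):
        spec = task_set[0]
        for trial_index, block in [(1, 1), (5, 1), (6, 2), (50, 10)]:
            t = make_trial(spec, spec.samples.copy(), trial_index=trial_index)
            assert t.block_index == block


def make_scores(values_ran, values_rep=None):
    values_rep = values_rep if values_rep is not None else values_ran
    return [
        TrialScore(trial_index=i + 1, task_id=1, agf_ran=values_ran[i], agf_rep=values_rep[i])
        for i in range(50)
    ]


class TestBlocksAndRates:
    def test_constant_scores_give_constant_blocks(self):
        blocks = block_means(make_scores([0.04] * 50))
        assert all(b.mean_agf_ran == pytest.approx(0.04) for b in blocks)

    def test_block_one_arithmetic(self):
        vals = [0.01, 0.02, 0.03, 0.04, 0.05] + [0.1] * 45
        blocks = block_means(make_scores(vals))
        assert blocks[0].mean_agf_ran == pytest.approx(0.03)

    def test_within_block_permutation_invariance(self, rng):
        vals = list(rng.uniform(0.01, 0.1, 50))
        base = block_means(make_scores(vals))
        shuffled = vals.copy()
        shuffled[0:5] = [vals[i] for i in (3, 1, 4, 0, 2)]
        perm = block_means(make_scores(shuffled))
        assert perm[0].mean_agf_ran == pytest.approx(base[0].mean_agf_ran)

    def test_partial_blocks_rejected(self):
        with pytest.raises(ValueError, match="50"):
            block_means(make_scores([0.01] * 50)[:49])

    def test_learning_rate_examples(self):
        def rates(m1, m10):
            blocks = [
                BlockScore(block_index=j, mean_agf_ran=m1 if j == 1 else m10,
                           mean_agf_rep=m1 if j == 1 else m10)
                for j in range(1, 11)
            ]
            return learning_rates(blocks)

        assert rates(0.05, 0.05).lr_ran == 0.0
        assert rates(0.080, 0.050).lr_ran == pytest.approx(60.0)
        assert rates(0.050, 0.080).lr_ran == pytest.approx(-37.5)
        with pytest.raises(UndefinedLearningRateError):
            rates(0.05, 0.0)

    @given(lam=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_learning_rate_is_dimensionless(self, lam):
        means = np.linspace(0.08, 0.03, 10)
        blocks = [
            BlockScore(block_index=j + 1, mean_agf_ran=means[j], mean_agf_rep=means[j])
            for j in range(10)
        ]
        scaled = [
            BlockScore(block_index=j + 1, mean_agf_ran=lam * means[j],
                       mean_agf_rep=lam * means[j])
            for j in range(10)
        ]
        assert learning_rates(scaled).lr_ran == pytest.approx(
            learning_rates(blocks).lr_ran, rel=1e-9
        )


class TestScoreParticipant:
    def test_matches_hand_composed_pipeline(self, task_set, schedule, rng):
        trials = []
        for t in range(1, 51):
            spec = {s.task_id: s for s in task_set}[schedule.trials[t - 1]]
            measured = np.clip(spec.samples + rng.normal(0, 0.02, 230), 0.0, 0.5)
            trials.append(make_trial(spec, measured, trial_index=t))
        scores, blocks, rates = score_participant(trials, task_set)
        by_task = {s.task_id: s for s in task_set}
        hand = [agf_random(t, by_task[t.task_id]) for t in trials]
        assert [s.agf_ran for s in scores] == pytest.approx(hand)
        m1 = float(np.mean(hand[:5]))
        m10 = float(np.mean(hand[45:]))
        assert rates.lr_ran == pytest.approx((m1 - m10) / m10 * 100.0)

    def test_perfect_tracker_raises_undefined_rate(self, task_set, schedule):
        trials = [
            make_trial(
                {s.task_id: s for s in task_set}[schedule.trials[t - 1]],
                {s.task_id: s for s in task_set}[schedule.trials[t - 1]].samples.copy(),
                trial_index=t,
            )
            for t in range(1, 51)
        ]
        with pytest.raises(UndefinedLearningRateError):
            score_participant(trials, task_set)
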