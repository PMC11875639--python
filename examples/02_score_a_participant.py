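"""Simulate one virtual participant and score their session.

The AGF score of a trial half is the mean absolute tracking error in kg
(lower = better); the learning rate is the percent error reduction from
block 1 to block 10, separately for the random half (external attention)
and the always-identical repeat half (internal attention).
"""

from gripletrack import cohort, scoring

specs = cohort.default_task_set()
schedule = cohort.default_schedule()
params = cohort.ParticipantParams(
    e0_rep=0.035, einf_rep=0.012, r_rep=0.93,   # strong repeat-half learning
    e0_ran=0.025, einf_ran=0.015, r_ran=0.93,   # milder random-half learning
)
trials = cohort.simulate_participant(specs, schedule, params, seed=42)
scores, blocks, rates = scoring.score_participant(trials, specs)

print("block  mean AGF random (kg)  mean AGF repeat (kg)")
for b in blocks:
    print(f"{b.block_index:>5}  {b.mean_agf_ran:20.4f}  {b.mean_agf_rep:20.4f}")
print(f"learning rates: LR_Ran = {rates.lr_ran:.1f}%  LR_Rep = {rates.lr_rep:.1f}%")
# Error decays across blocks; positive learning rates mean block 10
# tracked better than block 1.
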