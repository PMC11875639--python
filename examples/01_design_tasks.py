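"""Solve a feasible target-line set and inspect its boundary conditions.

Each of the five 23 s tasks holds 0.25 kg for 3 s, then follows its own
random-half waveform for 10 s and the shared repeat-half waveform for
10 s, all within 0.06-0.4 kg.
"""

from gripletrack import tasks

specs = tasks.build_task_set(seed=7)
report = tasks.validate_task_set(specs)

print(f"solved {len(specs)} tasks; all constraints pass: {report.passed}")
for spec in specs:
    f = spec.samples
    print(
        f"task {spec.task_id}: hold={f[0]:.3f} kg, "
        f"range=[{f[30:].min():.3f}, {f[30:].max():.3f}] kg, "
        f"junction step={abs(f[129] - f[130]):.4f} kg"
    )
# The hold is the 0.25 kg preparation level; the range must stay inside
# the 0.06-0.4 kg display window; the junction step is the one-sample
# increment where the random half hands over to the shared repeat half.
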