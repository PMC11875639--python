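"""Simulate the two calibrated cohorts and recover their learning rates.

The NC preset targets cohort-mean learning rates of 34.6% (random) and
71.8% (repeat); the MCI preset targets 30.8% and 28.5% — impaired
internal attention shows up as attenuated repeat-half learning only.
"""

import numpy as np

from gripletrack import cohort

nc = cohort.simulate_cohort_learning_rates(40, cohort.nc_preset(), seed=1)
mci = cohort.simulate_cohort_learning_rates(28, cohort.mci_preset(), seed=1001)

for label, res in (("NC ", nc), ("MCI", mci)):
    print(
        f"{label} (n={len(res['lr_ran'])}): "
        f"LR_Ran = {np.mean(res['lr_ran']):5.1f} ± {np.std(res['lr_ran'], ddof=1):4.1f} %   "
        f"LR_Rep = {np.mean(res['lr_rep']):5.1f} ± {np.std(res['lr_rep'], ddof=1):4.1f} %"
    )
# The random-half rates are similar across groups; the repeat-half rate
# collapses in the MCI cohort — the group signature the task is built
# to expose.
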