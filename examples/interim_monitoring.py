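"""Alpha-spending interim analysis with the adjusted statistic.

Because the control allocation is fixed per block, the adjusted statistic
can be computed at a pre-specified interim block S by truncating the
algorithm's horizon at S.  Spending the one-sided level over the looks
(Bonferroni) bounds the overall type I error by their sum.
"""

import numpy as np

from blockrar import (
    Scenario,
    SpendingPlan,
    alpha_spending_monitor,
    adjusted_statistic,
    interim_statistic,
    simulate_trial,
    standard_design,
)

design = standard_design(2)
scenario = Scenario(design=design, mus=(0.0, 0.2, 0.6), scheme="bar", seed=4)
trial, aux = simulate_trial(scenario, seed=4)

# spend 1% at the interim after block 1, the remaining 4% at the final block
plan = SpendingPlan(looks=(1, 3), levels=(0.01, 0.04))

arm = 2
interim = interim_statistic(trial, aux, S=1, arm=arm)
final = adjusted_statistic(trial, aux, arm=arm)
result = alpha_spending_monitor(plan, {1: float(interim.T), 3: float(final.T)})

print(f"interim T(1) = {float(interim.T):.3f}  (level 0.01 -> critical 2.326)")
print(f"final   T    = {float(final.T):.3f}  (level 0.04 -> critical 1.751)")
print(f"per-look decisions: {result.decisions}, stopped at: {result.stopped_at}")
print()
print("The monitor rejects at the first look whose statistic clears its")
print("own critical value; looks must be fixed in advance — testing at a")
print("data-chosen time would invalidate the calibration. Note the interim")
print("weights differ from the final ones:")
print("w (interim horizon):", np.round(interim.weights.w, 2))
print("w (full horizon)   :", np.round(final.weights.w, 2))
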