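"""Walk through the variance-matched weight calculation on a tiny trial.

A single experimental arm is compared against a control.  The auxiliary
(pre-fixed) design plans 4 patients per adaptive block; the realized
adaptive trial instead allocated 6 and then 3.  The weight trace shows how
each block's contribution is rescaled so the adjusted statistic keeps the
variance it would have had under the auxiliary design.
"""

import numpy as np

from blockrar import AuxiliaryDesign, compute_weight_trace

aux = AuxiliaryDesign(burn_in_counts=[2], alloc_counts=[[4], [4]])
realized = [6, 3]

wt = compute_weight_trace(aux, realized)

print("auxiliary counts per block :", aux.alloc_counts[:, 0], "burn-in:", aux.burn_in_counts[0])
print("realized counts per block  :", realized)
print("weights w0..wB             :", np.round(wt.w, 4))
print("contributions v0..vB       :", np.round(wt.v, 5))
print("sum of contributions       :", round(float(wt.v_sum), 5))
print()
print("w0 equals the auxiliary arm total (10). Block 1 was over-allocated")
print("(6 vs 4), so its weight rises to 10*sqrt(10/8) ~ 11.18, shrinking the")
print("block's per-patient contribution; the under-allocated final block is")
print("weighted down to ~9.68. The contributions v_j = realized/w_j no longer")
print("sum to 1 (here ~1.046) because the trial drifted from the plan; the")
print("adjusted statistic corrects for that with the control mean.")
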