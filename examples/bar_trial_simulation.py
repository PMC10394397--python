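"""Operating characteristics under Bayesian adaptive randomization.

Simulates the standard three-block, two-arm design (burn-in 5 per arm,
blocks of 40 experimental + 20 control) with BAR (gamma = 0.5) at true
means (0, 0.5) against a control at 0, and tabulates familywise error rate
and disjunctive power for all four analysis methods.  With one effective
arm, Holm beats the pooled closed z-test on power because the pooled
statistic is diluted by the ineffective arm.
"""

from blockrar import Scenario, operating_characteristics, standard_design

scenario = Scenario(
    design=standard_design(2),
    mus=(0.0, 0.0, 0.5),  # control, arm 1 (null), arm 2 (effective)
    scheme="bar",
    n_reps=20_000,
    seed=1,
)
summary = operating_characteristics(scenario)
print(summary)
print()
print("'error' is the % of trials rejecting the true null H1 (should stay")
print("near the nominal 5%); 'power' is the % rejecting the false null H2.")
print("Under BAR the naive and adjusted methods essentially coincide: this")
print("scheme happens not to inflate the naive test, and the adjustment")
print("costs no power. The *_se columns are binomial Monte-Carlo SEs.")
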