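"""Re-analysis of a dose-finding trial run with adaptive randomization.

Emulates a phase II placebo-controlled hypercholesterolemia trial: two
antibody+statin dose arms against a statin-only control, standardized true
means 17.3/3.5 (control), 66.2/3.5 (low dose) and 72.3/3.5 (high dose),
unit variance.  The trial allocates 8+8 experimental patients in the
burn-in and three BAR blocks of 15, with 31 control patients in total.
One simulated run is analyzed with the naive z and the adjusted statistic.
"""

from blockrar import case_study_run

report = case_study_run(seed=0)
print(report)
print()
print("With true mean differences of roughly 14 and 16 response SDs, both")
print("the naive z and the adjusted statistic are overwhelming (p < 0.001),")
print("so the adjustment changes nothing about the trial's conclusion; the")
print("weight traces show how far the realized allocation drifted from the")
print("uniform auxiliary plan. Each run of this script with another seed")
print("gives a different realized trial.")
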