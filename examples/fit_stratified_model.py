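"""Fit a stratified win-fractions regression to a simulated cohort.

Simulates a three-stratum cohort with a composite endpoint (death + first
nonfatal event), fits the pairwise win-ratio regression with within-stratum
comparisons only, and prints the inference table.  Each coefficient is a log
win ratio: exp(beta) > 1 means a unit increase in the covariate makes a
subject more likely to win (die later; failing that, have their first
nonfatal event later) against a comparable subject of the same stratum.
"""

import numpy as np

from stratwin import fit, gen_three_strata, wald_inference

rng = np.random.default_rng(42)
data = gen_three_strata(n=600, beta=(-0.5, 0.5), rng=rng)

model = fit(data, rule="pocock")
result = wald_inference(model, regime="finite")

print(f"converged in {model.iterations} Newton steps")
print(f"strata sizes: {model.n_per_stratum}")
print(result.summary_frame().to_string(index=False, float_format="%.3f"))
print(
    "\nTrue log win ratios were (-0.5, 0.5); the fitted win ratios should "
    "bracket exp(-0.5)=0.61 and exp(0.5)=1.65 within their CIs."
)
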