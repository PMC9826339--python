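"""Confounded exposure: naive, matched, and pair-stratified analyses.

A binary exposure whose probability depends on a prognostic covariate
confounds the plain two-sample win ratio.  Propensity-score matching
restores validity; stratifying the regression by matched pair additionally
adjusts for an independent predictor and gains power.
"""

import numpy as np

from stratwin import (
    diverging_strata_covariance,
    fit,
    gen_matching_design,
    pocock_two_sample_win_ratio,
)

rng = np.random.default_rng(11)
cohort, matched = gen_matching_design(n=600, gamma=0.5, beta1=0.0, rng=rng)

naive = pocock_two_sample_win_ratio(cohort, cohort.Z[:, 0] == 1.0)
paired = pocock_two_sample_win_ratio(matched, matched.Z[:, 0] == 1.0, matched=True)
model = fit(matched)
reg = diverging_strata_covariance(model)

print("true exposure effect: none (win ratio 1.00); confounding gamma=0.5\n")
print(
    f"unmatched win ratio : {naive.win_ratio:.2f} (p = {naive.p_value:.3f})"
    "  <- biased by confounding"
)
print(
    f"matched win ratio   : {paired.win_ratio:.2f} (p = {paired.p_value:.3f})"
    f"  [{len(matched.strata())} pairs]"
)
print(
    f"pair-stratified fit : WR {np.exp(model.beta[0]):.2f} "
    f"(p = {reg.p_values[0]:.3f}), adjusting for the extra predictor"
)
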