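"""Matched pairs: why the variance regime matters.

With strata of size two (matched pairs) the per-stratum asymptotics behind
the projection ("finite strata") variance estimator do not apply; the
stratum-sum ("diverging strata") estimator treats each pair as one
independent unit and stays honest.  This script fits the same matched-pair
data with both and compares their standard errors: the projection formula
is visibly larger (it overestimates here by roughly 40-50%).
"""

import numpy as np

from stratwin import (
    diverging_strata_covariance,
    finite_strata_covariance,
    fit,
    gen_frailty_strata,
)

rng = np.random.default_rng(3)
data = gen_frailty_strata(n=500, stratum_size=2, beta=(-0.5, 0.5), rng=rng)

model = fit(data)
div = diverging_strata_covariance(model)
fin = finite_strata_covariance(model)

print(f"{len(model.n_per_stratum)} informative pair-strata")
for k, name in enumerate(model.covariate_names):
    print(
        f"{name}: beta = {model.beta[k]:+.3f}; "
        f"SE diverging = {div.se[k]:.3f}, SE finite = {fin.se[k]:.3f} "
        f"(ratio {fin.se[k] / div.se[k]:.2f})"
    )
print(
    "\nThe diverging-strata SE is the one whose confidence intervals attain "
    "nominal coverage in this design."
)
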