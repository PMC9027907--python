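"""Posterior probability of treatment superiority at an interim analysis.

Simulates one interim dataset (37 completed subjects, true difference 0.05)
and evaluates Pr(treatment > control | data) under each prior community with
both estimators, plus the frequentist one-sided t-test p-value.
"""

import numpy as np

from commtrial import (
    ArmSummary,
    PosteriorSettings,
    VariancePrior,
    make_community,
    one_sided_p_value,
    prob_superiority,
)

rng = np.random.default_rng(7)
yc = rng.normal(0.00, 0.07, size=18)
yt = rng.normal(0.05, 0.07, size=19)
control, treatment = ArmSummary.from_samples(yc), ArmSummary.from_samples(yt)
vprior = VariancePrior()  # sigma^2 ~ Scaled-inv-chi2(weight 1, scale 0.07)

print(f"control  n={control.n} mean={control.mean:+.4f}")
print(f"treatment n={treatment.n} mean={treatment.mean:+.4f}\n")

gibbs = PosteriorSettings(estimator="gibbs_rao_blackwell", seed=11)
for label in ("skeptical", "enthusiastic", "noninformative"):
    com = make_community(label)
    p_quad = prob_superiority(control, treatment, com, vprior)
    p_gibbs = prob_superiority(control, treatment, com, vprior, gibbs)
    print(f"{label:14s} Pr(trt > ctrl): quadrature {p_quad:.4f}  gibbs {p_gibbs:.4f}")

print(f"\none-sided pooled t-test p-value: {one_sided_p_value(control, treatment):.4f}")
# The two estimators agree to ~1e-4. An early success stop would need the
# skeptical probability to exceed 0.998; an early futility stop would need the
# enthusiastic probability to drop below 0.70 -- neither fires on these data,
# so the trial would continue.
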