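"""Calibrate the Y90 effectiveness distribution to clinical response data.

Y90 monotherapy trials in hepatocellular carcinoma report 6-month RECIST
proportions of CR 79% / PR 20% / SD 0% / PD 0%.  This script fits the
(mu, sigma) of the [0,1]-truncated normal distribution of the
effectiveness q so that the simulated 6-month response profile of a
virtual cohort matches that target (a small cohort is used here to keep
the demo fast; the study-scale fit uses 10,000 patients).
"""

import numpy as np

from y90ici import CLINICAL_Y90_RESPONSE, fit_q_distribution

fit = fit_q_distribution(
    CLINICAL_Y90_RESPONSE, n=2000, dose=400.0, seed=1,
    mu_grid=np.linspace(0.04, 0.24, 6),
    sigma_grid=np.array([0.01, 0.04, 0.08]),
)

print(f"target profile:  CR {CLINICAL_Y90_RESPONSE.cr:.0%}  PR {CLINICAL_Y90_RESPONSE.pr:.0%}"
      f"  SD {CLINICAL_Y90_RESPONSE.sd:.0%}  PD {CLINICAL_Y90_RESPONSE.pd:.0%}")
print(f"fitted q ~ truncated N(mu={fit.mu:.3f}, sigma={fit.sigma:.3f}) on [0, 1]")
a = fit.achieved
print(f"achieved profile: CR {a.cr:.1%}  PR {a.pr:.1%}  SD {a.sd:.1%}  PD {a.pd:.1%}")
print(f"L1 objective {fit.objective:.3f} after {fit.evaluations} cohort simulations")
print(
    "\nThe mean effectiveness lands near 0.12: a 400 Gy prescription must act\n"
    "like ~48 Gy of uniform dose to reproduce the observed response mix."
)
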