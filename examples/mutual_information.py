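"""Estimate mutual information with the neural Donsker–Varadhan bound.

Draws correlated Gaussian pairs at three correlation levels and compares the
neural estimate with the closed form −½ ln(1 − ρ²). The estimator is the
same one used to score how much condition information a trained model's
shared code carries.
"""

import numpy as np

from biaae import MINESpec, estimate_mi

rng = np.random.default_rng(0)
n = 10_000
for rho in (0.0, 0.5, 0.9):
    a = rng.standard_normal(n)
    b = rho * a + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    estimate = estimate_mi(a[:, None], b[:, None], spec=MINESpec(seed=1))
    truth = -0.5 * np.log(1 - rho**2) if rho else 0.0
    print(f"rho={rho:3.1f}: estimated {estimate.value:6.3f} nats, "
          f"closed form {truth:6.3f} nats")
print("the estimate is a lower bound; agreement within ~0.1 nats at n=10k "
      "is typical for smooth low-dimensional dependence")
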