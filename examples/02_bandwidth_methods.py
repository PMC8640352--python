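"""Compare the six bandwidth selection methods on one sample.

Simulates one sample of 1000 test takers on an 80-item test, presmooths
it, and runs every selector.  The methods disagree substantially — which
is exactly the phenomenon the package exists to study.
"""

import numpy as np

from keq import select_bandwidth, DiscreteScoreDistribution
from keq.presmoothing import fit_loglinear_univariate

rng = np.random.default_rng(42)
x = np.arange(81.0)
latent = rng.beta(5, 2, size=1000)          # negatively skewed abilities
sample = np.rint(latent * 80).astype(int)
counts = np.bincount(sample, minlength=81).astype(float)

fit = fit_loglinear_univariate(x, counts, 4)
dist = DiscreteScoreDistribution(x, fit.fitted_probs, counts=counts, n=1000)

for method in ("penalty", "srt", "ds", "lcv", "plcv"):
    sel = select_bandwidth(dist, method)
    print(f"{method:8s} h = {sel.h:6.3f}")
sel = select_bandwidth(dist, "licv", n_repeats=50, seed=1, presmooth_degree=3)
print(f"{'licv':8s} h = {sel.h:6.3f}  (median of 50 half-split maximizers)")

# Small h (penalty, DS) track the score frequencies closely; SRT's
# normal-reference rule and LiCV's likelihood criterion prefer much
# smoother densities.
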