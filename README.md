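# keq — kernel equating with data-driven bandwidth selection

`keq` implements observed-score **kernel equating** (KE) of educational
test scores: making scores from two forms of a standardized test
interchangeable by mapping each form-X score to the form-Y score with the
same cumulative probability on a target population,

```
φ_Y(x) = G⁻¹(F(x)).
```

Because test scores are discrete, KE first *continuizes* the estimated
score distributions with a Gaussian kernel.  With score points `x_j`,
probabilities `r_j`, mean `μ`, variance `σ²` and bandwidth `h`, the
continuized CDF is

```
F_h(x; r) = Σ_j r_j Φ((x − a x_j − (1 − a) μ) / (a h)),    a² = σ²/(σ² + h²),
```

where the shrinkage factor `a` makes the continuized variable preserve the
first two moments of the discrete distribution for every bandwidth.  Tiny
bandwidths reproduce classical equipercentile equating with linear
interpolation (h ≈ 0.33) and huge bandwidths reproduce linear equating, so
the bandwidth spans the whole family of traditional methods.

The package is for psychometricians and statisticians studying (or
practicing) score equating.  It provides:

* log-linear (polynomial Poisson) **presmoothing** of univariate and
  bivariate score frequencies with AIC/BIC model search and the covariance
  factor needed for standard errors (`keq.presmoothing`);
* six **bandwidth selectors** — penalty, Silverman's rule of thumb (SRT),
  double smoothing (DS), likelihood cross-validation (LiCV), leave-one-out
  cross-validation (LCV) and penalized LCV (PLCV) (`keq.bandwidth`);
* **equating** under the equivalent-groups (EG) design and the
  non-equivalent-groups anchor-test (NEAT) design with post-stratification
  (`keq.equating`);
* **evaluation**: delta-method and bootstrap standard errors of equating
  (SEE), percent relative error (PRE) of moments, MSE/SE summaries and
  difference-that-matters (DTM) flags (`keq.evaluation`);
* a replicated **simulation study** runner with a beta/Gaussian-copula
  data-generating process (`keq.simulation`);
* TSV/CSV frequency-table I/O and a small `keq` command line
  (`keq.io`, `keq.cli`).

## Worked example

Select bandwidths for a presmoothed 80-item score distribution
(`examples/02_bandwidth_methods.py`):

```python
import numpy as np
from keq import select_bandwidth, DiscreteScoreDistribution
from keq.presmoothing import fit_loglinear_univariate

rng = np.random.default_rng(42)
x = np.arange(81.0)
sample = np.rint(rng.beta(5, 2, size=1000) * 80).astype(int)
counts = np.bincount(sample, minlength=81).astype(float)
fit = fit_loglinear_univariate(x, counts, 4)
dist = DiscreteScoreDistribution(x, fit.fitted_probs, counts=counts, n=1000)
for method in ("penalty", "srt", "ds", "lcv", "plcv"):
    sel = select_bandwidth(dist, method)
    print(f"{method:8s} h = {sel.h:6.3f}")
```

prints

```
penalty  h =  0.600
srt      h =  3.021
ds       h =  0.540
lcv      h =  5.410
plcv     h =  5.410
```

The selectors disagree by an order of magnitude: the penalty and DS
criteria track the score frequencies closely (h ≈ 0.6), while SRT's
normal-reference rule smooths five times harder.  Running the replicated
experiment (`examples/05_simulation_study.py`) shows the punchline of the
methodology study this package reproduces: despite those very different
bandwidths, the MSE of the equated mean is nearly identical across
methods — the equating transformation is robust to the bandwidth choice,
while sample size and test length matter far more.

The other examples cover continuization moments (`01`), NEAT
post-stratification equating with standard errors (`03`), and the
analytical-vs-bootstrap SEE comparison (`04`).

## Command line

```sh
keq bandwidth --method penalty --input freq.tsv --presmooth-degree 4
keq equate --design neat-pse --x p.tsv --y q.tsv --weight 0.5 --bandwidth-method ds
keq simulate --design neat --shape neg_skew --n 1000 --reps 200 --seed 1 --out out/
keq bootstrap-see --x x.tsv --y y.tsv --b 1000 --seed 1
```

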