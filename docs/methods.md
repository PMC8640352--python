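# Methods

## The model

Kernel equating treats the scores on two test forms X and Y as discrete
random variables on integer grids `0..J−1` and `0..K−1` with
target-population probabilities `r` and `s`.  The equipercentile
transform `φ_Y(x) = G⁻¹(F(x))` needs continuous, strictly increasing
CDFs, so each discrete distribution is replaced by the Gaussian-kernel
continuization

    X(h) = a (X + h Z) + (1 − a) μ,   a² = σ² / (σ² + h²),

whose CDF is `F_h(x; r) = Σ_j r_j Φ((x − a x_j − (1−a) μ)/(a h))`.  The
shrinkage factor `a` preserves the mean and variance of `X` exactly for
every bandwidth `h`; as `h → 0` the CDF approaches the discrete step
function and as `h → ∞` it approaches the normal with the same first two
moments (so equating approaches linear equating).  `h ≈ 0.33`
approximates classical percentile-rank equating with linear
interpolation.

Estimation follows the standard five-step KE pipeline: presmoothing,
score-probability estimation (the design function), continuization,
equating, evaluation.

### Presmoothing

Score frequencies are smoothed by polynomial Poisson (log-linear)
models: `log E[n_j] = β₀ + Σ_{d≤T} β_d x_j^d`, fitted by maximum
likelihood (statsmodels GLM; monomial columns are standardized for
conditioning, which does not change the fit).  The score equations make
the fitted distribution reproduce the observed raw moments of every
order in the design — the property our tests assert to 1e-6.  Bivariate
tables add anchor polynomials and selected cross-moment terms `x^i a^j`.
Model search minimizes AIC (`−2ℓ + 2k`, univariate) or BIC
(`−2ℓ + k log n`, `n` = total count, bivariate) over the candidate
family: univariate degrees 2–6; bivariate marginal degrees 2–4 crossed
with cross-moment sets {}, {(1,1)}, {(1,1),(1,2),(2,1)}, {(1,1),(2,2)}.

The asymptotic covariance of the fitted probability vector is
`(1/n) S B (BᵀSB)⁻¹ BᵀS` with `S = diag(p) − ppᵀ` and `B` the
intercept-free design; `cov_factor` returns a matrix square root `C`
of it (Cholesky-based).  For a saturated design this collapses to the
multinomial covariance, which is also what the no-presmoothing SEE uses.

### Design functions

EG: both samples estimate the target population directly; the design
function is the identity.  NEAT with post-stratification (target
`T = wP + (1−w)Q`, default `w = 0.5`):

    r_j(T) = Σ_l Pr(X = x_j | A = a_l, P) [w Pr(A = a_l|P) + (1−w) Pr(A = a_l|Q)]

and symmetrically for `s`.  Conditionals are taken from presmoothed
joint fits, whose strict positivity guarantees nonzero anchor margins.

### Bandwidth selection

All selectors operate on the (presmoothed, post-stratified) probability
vector; only LiCV additionally resamples raw individuals.

* **penalty** — minimizes `Σ_j (r_j − f_h(x_j))² + κ Σ_j A_j` with
  `κ = 1`, `w = 0.25`.  `A_j` flags a sign change of the density
  derivative between `x_j − w` and `x_j + w`.  The default counts
  U-shapes only (derivative negative left, positive right): an
  undersmoothed density has valleys near low-probability score points,
  and the count returns to zero once `h` is large enough.  Counting
  flips in both directions (`flip="both"`) is available but makes the
  criterion hostage to the genuine mode, which keeps one flip alive at
  the nearest score point for almost every `h`; see "Judgment calls".
* **SRT** — closed form `h = 9σ / sqrt(100 n^{2/5} − 81)`, the unique
  solution of `a(h)·h = 0.9 σ n^{−1/5}` (Silverman's normal-reference
  rule applied to the effective kernel scale `a·h`).
* **DS** — double smoothing.  A large pilot bandwidth `q` (default
  3× SRT) gives a pilot density; its values at the score points,
  renormalized to sum to one, replace the probabilities as mixture
  weights of the double-smoothed estimate `f*_h`.  The criterion sums
  squared deviations over the interleaved grid of scores and midpoints
  (`2J − 1` points), targeting the observed probabilities at score
  points and the pilot density at midpoints.
* **LiCV** — repeated random half-splits of the test takers (sizes
  ⌈n/2⌉ and ⌊n/2⌋).  The training half yields a kernel density `f⁽¹⁾`;
  the validation half's frequencies enter a Poisson likelihood with
  intensities `N⁽¹⁾ f_h⁽¹⁾(x_j)`, maximized over the grid
  `h ∈ {0.01, …, 5}`; the median over repeats (default 1000) is
  returned.  The simulation runner presmooths the training half with a
  univariate log-linear model matching the scenario's marginal moment
  design, following the method's source procedure; with raw empirical
  training halves the likelihood is almost always maximized at the top
  of the grid (see "Judgment calls").
* **LCV / PLCV** — leave-one-out: `LCV(h) = (1/J) Σ_j (r_j −
  f_h^{−j}(x_j))²` where `f^{−j}` drops component `j` without
  renormalizing, with `a` and `μ` from the full vector.  PLCV adds the
  same `κ Σ A_j` penalty as the penalty method.

Grid-based selectors minimize by a dense two-stage grid on
`[0.01, 30]`: coarse step 0.05 (float32 pass, enough to locate a basin)
then step 0.001 in the winning interval (float64).  A grid is used
instead of a line search because the penalty term makes the objective a
step function; the contract, asserted by tests, is agreement with an
exhaustive 0.001-step search within one step.  LiCV evaluates every
fifth grid point first and then the full grid in the winning window,
which is exact for the unimodal likelihood profiles it encounters.

### Standard errors

The delta-method SEE is `SEE_Y(x) = ‖J_φ J_DF C‖` per score point.
`J_φ` uses the closed-form derivatives of `F_h` with respect to `r`
*including* the dependence of `a` and `μ` on `r` — writing
`z_j(x) = (x−μ)/(ah) + (μ−x_j)/h` shows `∂z_j/∂r_m` is the same for all
`j`, so `∂F/∂r_m = Φ(z_m) + D_m(x)·a·h·f_h(x)` with an explicit `D_m`.
A finite-difference cross-check (step 1e-6) is in the test suite.
`J_DF` is the identity for EG and the analytic post-stratification
Jacobian for NEAT (also finite-difference checked).  Bandwidths are
treated as known constants; the nonparametric bootstrap SEE
(`see_bootstrap`, EG pipeline) re-selects bandwidths per resample and
therefore includes their variability — the two agree in the mid-range
(0.05 ≤ F̂ ≤ 0.95) and diverge in the tails, which the acceptance suite
asserts at n = 10,000 with B = 1000.

Where the continuized density at the equated score falls below 1e-12
(extreme tails) the SEE denominator is floored at that value rather
than raising, and the value is returned; tail SEEs are unreliable there
in any implementation.

### Evaluation statistics

`PRE(p) = 100 (μ̂_p(φ_Y(X)) − μ_p(Y))/μ_p(Y)` for p = 1..10;
`MSE(μ̂_Y) = [mean_g(μ̂⁽ᵍ⁾) − μ_Y]² + (G−1)⁻¹ Σ_g (μ̂⁽ᵍ⁾ − mean)²`;
per-score SE uses the same G−1 divisor; DTM flags differences strictly
greater than half a raw-score unit.

## Simulation design

One scenario = design (EG / NEAT) × shape × n × test length × anchor
length.  Latent abilities are Beta(5,5) (symmetric), Beta(5,2)
(negative skew), Beta(2,5) (positive skew) or an equal mixture of
Beta(25,15) and Beta(15,25) (bimodal); NEAT couples form and anchor
abilities through a Gaussian copula with correlation 0.75 (the induced
product-moment correlation of the discrete scores is slightly lower).
Scores are `round(latent × length)`.  The *truth* is the fitted
probability vector of a log-linear model on one such sample — smooth,
positive, and generated once per scenario.  Fixed designs follow the
study being reproduced: EG degree 2 (symmetric) / 3 (skewed, bimodal);
NEAT marginal degree 4 with cross-moments (1,1),(2,2) for symmetric and
negatively skewed shapes, degree 2 with (1,1) for positive skew and
bimodal; AIC/BIC search is available as an option.  Population Q's form
score is shifted +5 units after rounding, clamped to the grid (the
anchor is common and unshifted), so the identity is never the true
equating function — the runner asserts this on every truth.

Each replicate draws multinomial frequencies from the truth, presmooths
with the truth's design, applies the design function, selects
bandwidths per method, equates, and accumulates `μ̂_Y = Σ_j φ̂(x_j) r_j`
(true-`r` weighting), the equated curves and the selected bandwidths.
Default G = 1000 replications; the acceptance runs use G = 200 and
LiCV limited to 100 replicates × 100 splits, which keeps the two
headline scenarios near ten minutes on one CPU while the Monte-Carlo
standard error of a mean bandwidth stays well below the comparison
tolerances.

What the generator does *not* emulate: item-level response processes
(scores are rounded latents, not sums of Bernoulli items), so
test-length effects on score-distribution shape and anchor reliability
are absent; real anchors embedded in real forms; examinee-population
drift.  Passing tests therefore show the pipeline reproduces the
stated stochastic model, not that any method is best on real data.

## Judgment calls

Three places in the source description are internally inconsistent; in
each case the package follows the resolution that reproduces the
study's own reported numbers, keeps the printed variant available, and
the tests document the behavior:

1. **Penalty flip direction.**  As printed, `A_j` counts flips in both
   directions.  A unimodal continuized density then almost always keeps
   one mode-flip alive near a score point, the count never settles at
   zero, and with κ = 1 the selected bandwidth is driven to ~3 rather
   than the reported ~0.6.  The U-shape-only count (the definition in
   the penalty method's source literature) makes the penalty inert on
   smooth presmoothed input and active exactly on undersmoothed input,
   and reproduces the reported behavior.  Default `flip="dip"`.
2. **LiCV training density.**  With raw empirical training halves the
   Poisson likelihood is maximized at the top of the bandwidth grid in
   nearly every split (median pinned at 5.0 with near-zero variance),
   contradicting the reported interior mean and the observation that
   LiCV has the largest variance under NEAT.  Presmoothing the training
   half (as in the method's source procedure) yields interior, widely
   dispersed maximizers.  The standalone selector defaults to raw; the
   simulation runner presmooths.
3. **LCV monotonicity.**  The leave-one-out criterion as printed is
   monotone decreasing in `h` on every input we generated (presmoothed
   or raw, any design or sample size): removing the own component makes
   undersmoothing costless while oversmoothing stays nearly costless on
   smooth inputs.  Its minimizer is therefore a property of the search
   range, not the data, and the reported small LCV bandwidths (~0.33)
   are not reproducible from the printed formula.  The package
   implements the printed formula faithfully and documents the
   discrepancy rather than substituting a guessed criterion; PLCV
   inherits the behavior wherever the penalty count is zero.

Other numerical choices: probabilities are validated to sum to one
within 1e-6 and renormalized only for sub-1e-8 violations; degenerate
distributions (σ² = 0 or a single score point) raise; quantiles use
Brent root-finding on a bracket padded by 10(h+σ) with tolerance 1e-12;
equated CDF values are clipped to (1e-15, 1−1e-15) before inversion;
master seeds expand through `numpy.random.SeedSequence` into truth,
replicate and split seeds, so every run is reproducible from one
integer.

## Known limitations

* The analytical SEE does not account for bandwidth-selection
  variability (by construction); only the bootstrap does.
* `see_bootstrap` covers the EG univariate pipeline; a NEAT bootstrap
  would re-run the bivariate pipeline per resample.
* Gaussian kernels only; no adaptive per-point bandwidths; no chained
  equating or IRT-based kernel equating.
* The anchor-length effect on MSE reported for the original study does
  not emerge from this DGP: with the copula correlation fixed at 0.75,
  doubling the anchor grid leaves post-stratification variance
  essentially unchanged.
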