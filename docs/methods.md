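# Methods

## Model and estimation

Both functional forms are estimated on the log scale, where they are linear
in the parameters. The dependent variable is ln(patient-days), with
patient-days kept in thousands and the inputs in their natural units (bed
count, FTEs, costs in 100,000 PLN). Elasticities are unit-free, so this
choice only fixes the units in which marginal products and growth rates are
read: a marginal product of electricity of 2.25 means 2.25 *thousand*
patient-days per 100,000 PLN.

The translog is parameterised with a symmetric quadratic block: diagonal
coefficients multiply $(\ln x_k)^2$, off-diagonal coefficients multiply the
cross product $\ln x_k \ln x_l$ once. The packed coefficient/term order is
fixed (intercept; linear terms in input order; squares in input order;
crosses in lexicographic pair order), so fits are bit-for-bit reproducible
and serialise to flat JSON keys (`ln_beds`, `ln_beds^2`,
`ln_beds*ln_nurses`). The translog's linear terms are in $\ln x$, which is
what makes it nest the Cobb-Douglas exactly at zero quadratic block, and
its elasticity is $E_k = a_k + 2 b_{kk}\ln x_k + \sum_{l\ne k} b_{kl}\ln
x_l$ — note the linear coefficient $a_k$ is part of the bracket.

OLS fits go through a numerically stable orthogonal decomposition
(statsmodels); a rank-deficient design raises an error naming the collinear
terms (identified by pivoted QR), and a condition number above 1e8 on the
column-scaled design triggers a warning. Inference is the two-sided t test
of each coefficient against zero at $df = n - p$; residual standard error
is $\sqrt{RSS/df}$ on the log scale, for the robust fit too, so that fit
comparison across methods reads the same quantity (the Huber fit's robust
scale estimate is kept separately in `scale_`).

Huber M-estimation uses IRLS with tuning constant $c = 1.345$ and scale =
MAD/0.6745 re-estimated each iteration, at most 50 iterations with
convergence on the coefficient change — the conventional defaults of robust
regression software, documented here as a compatibility target rather than
a bit-exact one. Standard errors are the asymptotic (weighted information)
ones, with normal rather than t reference; with n near 94 and 3–10
parameters the difference is immaterial for counting significant terms.
Significance counting uses strict $p < \alpha$ with $\alpha = 0.05$ by
default and no multiple-testing correction (none is applied in this kind of
per-model reporting).

## Derived economics

All derived quantities are evaluated at the *model-fitted* output level
$f(x)$, never at the observed mean of $y$; this is what makes the identity
chain $T_i = E_i f(x)/x_i = S_i f(x)$ hold exactly and is required for the
internal consistency of reported marginal products and elasticities.
Default evaluation points are the component-wise raw-scale sample means and
medians of the estimation sample. Growth rates and elasticities are
returned as raw proportions; the narrative layer attaches percent labels.

The MRTS $\sigma_{ij} = T_i/T_j$ is reported for ordered pairs and
satisfies $\sigma_{ij}\sigma_{ji} = 1$; it is undefined (explicit error)
when the denominator elasticity is zero. The elasticity of substitution is
reported only for the Cobb-Douglas form, where it is identically 1;
requesting it for a translog raises an explicit unsupported-form error
rather than returning an Allen or Morishima measure the reporting layer
does not define.

Validity flagging implements producer rationality: a production function is
accepted at an evaluation point iff every elasticity (equivalently, every
marginal product) is non-negative there; violations are listed by input.
For a Cobb-Douglas fit a negative exponent therefore invalidates the model
at *every* point.

## Model space and comparison

Admissible specifications are all 2- and 3-element subsets of {beds,
materials, electricity, doctors, nurses, services} containing at least one
of {beds, doctors, nurses}: 12 pairs and 19 triples, verified against a
brute-force bitmask enumeration. Identifiers M1… are assigned in
lexicographic subset order over the canonical input order; the original
study never states its own numbering, so the mapping of our M10/M19 onto
its M10/M19 is a convention, not a verified correspondence — the worked
examples are pinned to input sets, not labels.

Comparison tables aggregate, for each input, over exactly the fitted models
whose specification contains it: median/min/max residual standard error and
mean/median number of significant non-intercept coefficients. Subsampling
keeps hospitals with beds between the first and third sample quartiles
inclusive (quartiles by linear interpolation of order statistics) plus any
boolean attribute filters present in the data.

## Synthetic data generator

The generator emulates a hospital cross-section, not any particular
hospital system. On the log scale each input is a linear factor model,
$\ln x_k = \mu_k + \lambda_k \ln S + \varepsilon_k$ with a standard-normal
latent size $\ln S$ shared across inputs; output is the chosen production
function times a lognormal disturbance. This multiplicative design makes
OLS on logs the maximum-likelihood estimator, so parameter recovery is a
clean test of the estimation stack.

The shipped calibration matches the shape of the study population: per
column, $\mu_k = \ln(\text{median})$ and total log-sd
$\sigma_k = \sqrt{2\ln(\text{mean}/\text{median})}$ (the lognormal
mean/median relation), split as $\lambda_k = 0.8\sigma_k$ and idiosyncratic
sd $0.6\sigma_k$, giving pairwise log-correlations of 0.64. Defaults:
n = 94 hospitals, log-output noise sd 0.15 (the residual scale of the
better-fitting models in this literature), and a default technology that is
Cobb-Douglas over all six inputs with exponents summing to 0.90 —
decreasing returns to scale, as hospital samples typically show — and
intercept placed so the median output is ≈53 thousand patient-days.
Exact moment matching is a non-goal; only orderings (mean > median, bed
scale) are calibration targets. Contamination is opt-in: a seeded fraction
of rows has its log disturbance multiplied by `outlier_scale`, drawn so
that toggling the fraction changes only the flagged rows.

What the generator does *not* emulate: staffing-regulation constraints
linking staff to beds, ownership/ED/ICU composition effects, the extreme
single-hospital staffing outliers present in real registries, or any panel
dimension. Passing tests therefore demonstrate correctness of the
estimators and economics under a well-specified multiplicative DGP, not
robustness to real-data misspecification.

## Numerical conventions and checks

- Natural logarithms throughout; sample sd uses the n−1 denominator; even-n
  medians are midpoints of the central order statistics.
- Analytic elasticities, marginal products and scale derivatives are tested
  against central-difference numeric derivatives at relative step 1e−6.
- Simulation-based checks run at the study's conditions: 500 replicates for
  OLS recovery (n = 94, noise sd 0.15, bias tolerance ±0.02), 200
  replicates for the Huber-vs-OLS contamination comparison (≥80% wins) and
  for the "beds-driven output puts beds first in the comparison table"
  property (≥90% wins).
- Full-pipeline outputs are deterministic given seed and configuration and
  every artifact is stamped with the seed and a configuration hash.

## Known limitations

- No stochastic-frontier, DEA or efficiency-score machinery; the package
  characterises the fitted technology, not inefficiency.
- No heteroskedasticity-robust covariances or model-selection criteria
  (AIC/BIC); fit comparison is by residual standard error, as in the
  reporting convention this package mirrors.
- Translog substitution elasticities (Allen/Morishima) are out of scope.
- The Huber fit reproduces conventional software behaviour but is not
  guaranteed bit-identical to any particular implementation.
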