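# Methods

## Model and assumptions

Individuals carry 0 or 1 copies of an index allele; carrier status `G`
is assigned at birth with probability `p0` and is fixed for life.
Mortality follows a Gompertz proportional-hazards law,
`mu(x|G) = exp(log_a + b*x + gamma*G)`: the baseline doubles roughly
every `ln 2 / b ≈ 8.7` years at the default `b = 0.08`, and the allele
multiplies the hazard by `exp(gamma)` at every age.  Assumptions worth
making explicit:

* individuals are independent (no family structure, although the study
  design this emulates is family-based);
* the allele's effect is proportional and constant in age — no
  trade-off or crossing survival curves, although the joint likelihood
  itself would detect such patterns through parameter estimates if the
  hazard model were extended;
* entry age equals age at biospecimen collection, and censoring is
  purely administrative at entry + follow-up length;
* no genotyping error, no dropout, no secular trends in mortality.

## The two likelihoods

Write `u`, `x`, `delta` for entry age, exit age and event indicator,
and `H`, `S` for the Gompertz cumulative hazard and survival.

**FU** conditions on survival to entry and on the observed genotype:
`l_FU = sum delta*ln mu(x|g) - (H(x|g) - H(u|g))`.  This is the fully
parametric analogue of the standard baseline-age-adjusted survival
regression; `p0` does not appear.

**FU+A** adds the probability of the observed genotype given survival
to the entry age, `ln pi_g(u)` with
`pi_1(u) = p0*S(u|1) / (p0*S(u|1) + (1-p0)*S(u|0))`.  Given the design
(entry ages assigned independently of genotype and lifespan), the
distribution of entry ages among enrollees is parameter-free, so the
conditional likelihood of `(g, x, delta | u)` factorizes into exactly
these two terms; nothing else about the observed data carries
information about the parameters.  `p0` is a free parameter of the
FU+A fit.  The increment depends only on `(g, u)` pairs — a structural
identity the tests assert.

The FU and FU+A maximized log-likelihoods live on different data scales
(the genotype term) and are never compared to each other; likelihood
ratios are always within one method, against its own `gamma = 0` refit.

## Estimation and numerics

* Internal coordinates `(log_a, log b, gamma, logit p0)` enforce
  positivity and range constraints without bounded optimization.
* L-BFGS-B with numerically estimated gradients, objective tolerance
  1e-12; a Nelder–Mead pass rescues or polishes the rare stall.  The
  truth-agnostic default start is `log_a = -8`, `b = 0.1`, `gamma = 0`,
  `p0 =` observed carrier fraction.
* Standard errors: central-difference Hessian (step 1e-4 per internal
  coordinate) at the optimum, inverted and delta-method mapped to the
  reporting scale (`b` by a factor `b`, `p0` by `p0(1-p0)`).
* The cumulative hazard switches to a log-space form when `b*x > 700`,
  where `exp(b*x)` would overflow; irrelevant at human ages but the
  optimizer may probe extreme parameters.
* Lifespans are drawn by exact inverse-CDF sampling,
  `T = (1/b)*log1p(-b*ln U / exp(log_a + gamma*g))`; a zero uniform
  draw (probability ~1e-308) is nudged to the smallest positive float.
* Ages are continuous non-negative reals with no upper cap: at the
  default parameters survival beyond ~115 is negligible.
* Fits are rejected up front for cohorts with no events or a single
  genotype, where `gamma` is not identifiable.
* A lifespan exactly equal to the censoring horizon (probability zero)
  counts as an observed death; enrollment requires lifespan strictly
  greater than entry age.

## Simulator

Default generating conditions: `log_a = -9`, `b = 0.08`, `p0 = 0.25`,
4500 enrolled survivors, entry ages equiprobable on the 61 integers
40–100, 6 years of follow-up.  Two sampling schemes are provided.
*Rejection* mode (default) draws (genotype, entry age, lifespan)
triples and keeps survivors until the target size is reached.
*Population* mode materializes a large population once, filters
survivors, and subsamples uniformly — the scheme described for the
original study, retained at reduced size as a validation path.  For
i.i.d. individuals the two are distributionally identical, which the
test suite checks by chi-square homogeneity of (age bin, genotype,
event) tables across 20 paired runs.  Rejection mode makes
1000-replicate grids cheap: the acceptance fraction at these parameters
is ≈ 0.55, so a 4500-person cohort costs ≈ 8200 draws instead of ten
million.

Entry ages are read as the 61 integers 40..100 inclusive; the design
statement ("discrete, uniform on 40–100") does not fix the step or
endpoint convention, and integer years with inclusive endpoints is the
natural reading.

What the simulator does **not** emulate: within-family correlation of
genotype and lifespan, genotyping error, non-administrative dropout,
delayed biospecimen collection relative to baseline, secular mortality
trends.  Passing tests therefore demonstrate the statistical behaviour
of the estimators under the stated design, not robustness of the method
on real cohort data.

## Seeding

Every stochastic operation takes an explicit `numpy.random.Generator`.
Replicate `r` of the scenario with effect `gamma` under master seed `s`
uses `SeedSequence([s, round(1000*gamma) mod 2^31, r])`, so any single
replicate is reproducible in isolation and scenario runs are
order-independent.

## Power study

Each scenario simulates `n_reps` cohorts, fits both methods, and
records the mean and SD of the gamma estimates and the fraction of
replicates with two-sided Wald p < alpha (default 0.05).  The Wald test
is the working rejection rule because the empirical power is then
directly comparable to the one-sample Z-test power curve

    w(gamma; sigma, alpha) = Phi(-z_{1-alpha/2} + gamma/sigma)
                           + Phi(-z_{1-alpha/2} - gamma/sigma)

used to summarize each method by a single best-fit sigma (unweighted
least squares over the grid; the `gamma = 0` point is uninformative
about sigma but harmless).  Likelihood-ratio-test power can be computed
alongside (`include_lrt=True`; on by default in the `reproduce`
command, off in the library call since it doubles the number of fits),
and on null scenarios the two rules agree in ≥ 95% of replicates.
Level-of-test curves invert `w` in `alpha` by monotone root finding on
`log10(alpha)`.

Non-converged replicates are dropped and counted; more than 5% of them
in a scenario raises an error, since at these sample sizes the
likelihood surface is smooth and such failures indicate a defect, not
noise.  In practice none occur.

The scenario summary reports the SD average both over the full grid and
over the non-zero effects only; at these designs the two differ by less
than the Monte-Carlo error, so either convention supports the same
conclusions.

## Problem sizes

Default replication is `n_reps = 1000` per scenario, the full design.
The test suite runs a reduced grid `{-0.4, -0.2, 0, 0.2, 0.4}` at 500
replicates per scenario (the package's desk-scale setting) — SD
estimates then carry a chi-distribution standard error of about
`sigma / sqrt(2*500) ≈ 0.003`, comfortably inside the tolerances
asserted.  The acceptance script runs the single `gamma = 0.4` scenario
at the full 1000 replicates (about a minute on one CPU).

## Known limitations

* The Gompertz baseline is the only hazard family implemented; no
  Makeham term, no Weibull alternative.
* Exactly two genotype classes; allele-dose (0/1/2) models are out of
  scope.
* Independent subjects only; family-based designs need
  relatedness-aware extensions.
* The MLE of `gamma` shows a small finite-sample bias (|bias| < 0.01 at
  n = 4500) at intermediate effect sizes, ordinary for parametric
  survival MLEs at these event counts; tests assert unbiasedness within
  Monte-Carlo resolution at `gamma in {-0.4, 0, 0.4}`.
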