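# jointsurv

Joint analysis of prospective follow-up mortality data and the ages at
biospecimen collection, for detecting genetic effects on human lifespan.

## The problem

Genetic association studies of longevity usually analyse prospective
cohort data with a survival regression conditioned on age at baseline.
When baseline coincides with biospecimen collection — as in the Long
Life Family Study and most CHARGE-type cohorts — that conditioning
discards real information: in a genetically heterogeneous population,
mortality selection makes the carrier frequency of a lifespan-affecting
allele change systematically with age among the living.  An old
participant being a carrier (or not) is itself evidence about the
allele's effect.  Conditioning it away is one reason longevity GWAS
findings so often miss genome-wide significance.

`jointsurv` implements both estimators so the gain can be measured:

* **FU** (follow-up only): the conventional approach — the parametric
  likelihood of exit times given survival to the entry age (left
  truncation) and the observed genotype.
* **FU+A** (follow-up + age structure): the joint likelihood that
  multiplies in, per subject, the probability of the observed genotype
  given survival to the age at biospecimen collection.

## Model

Carriers (G = 1) and non-carriers (G = 0) of an index allele follow a
Gompertz proportional-hazards law

```
mu(x | G) = mu0(x) * exp(gamma * G),      ln mu0(x) = ln a + b x,
```

with `P0 = P(G = 1)` the carrier proportion at birth.  With entry age
`u_i`, exit age `x_i` and event indicator `delta_i`, the two
log-likelihoods are

```
l_FU  = sum_i [ delta_i ln mu(x_i|G_i) - (H(x_i|G_i) - H(u_i|G_i)) ]
l_FUA = l_FU + sum_i ln pi_{G_i}(u_i),
pi_1(u) = P0 S(u|1) / (P0 S(u|1) + (1 - P0) S(u|0)),
```

where `H` and `S` are the Gompertz cumulative hazard and survival and
`pi_1(u)` is the carrier frequency among survivors to age `u`.  `P0` is
a free parameter of the FU+A fit.  `gamma = 0` (coincidence of carrier
and non-carrier survival) is tested by Wald or likelihood-ratio tests.

The built-in simulator generates cohorts under the reference design:
`ln a = -9.0`, `b = 0.08`, `P0 = 0.25`, 4500 enrolled survivors with
integer entry ages uniform on 40–100 and administrative censoring 6
years after entry.

## Worked example

```python
import numpy as np
from jointsurv import (GompertzGenoModel, SimulationDesign, simulate_cohort,
                       fit_mle, test_gamma, survivor_carrier_frequency)

model = GompertzGenoModel(log_a=-9.0, b=0.08, gamma=0.4, p0=0.25)
design = SimulationDesign(model=model)          # n=4500, entry 40-100, 6 y follow-up
cohort = simulate_cohort(design, np.random.default_rng(42))
print(f"events: {cohort.event.sum()}, carrier fraction: {cohort.g.mean():.3f}")
print(f"carrier freq at 40 vs 100: "
      f"{survivor_carrier_frequency(model, 40.0):.3f} vs "
      f"{survivor_carrier_frequency(model, 100.0):.3f}")

for method in ("FU", "FUA"):
    fit = fit_mle(cohort, method)
    z, p = test_gamma(fit, kind="wald")
    print(f"{method:3s}: gamma = {fit.estimates['gamma']:.3f} "
          f"(SE {fit.std_errors['gamma']:.3f}), Wald p = {p:.2e}")
```

prints

```
events: 747, carrier fraction: 0.233
carrier freq at 40 vs 100: 0.247 vs 0.034
FU : gamma = 0.330 (SE 0.086), Wald p = 1.28e-04
FUA: gamma = 0.430 (SE 0.056), Wald p = 2.15e-14
```

The deleterious allele (true `gamma = 0.4`) depletes carriers with age
(24.7% of survivors at 40, 3.4% at 100).  Both fits recover the effect,
but the joint likelihood estimates it with a standard error about a
third smaller (0.056 vs 0.086), which here moves the p-value by ten
orders of magnitude.  Across many replicates this is the difference
between a signal lost and genome-wide significance.

## Command line

```
jointsurv simulate  --out cohorts/ --seed 1          # write cohort CSVs + manifest
jointsurv fit cohorts/cohort_0000.csv --method fua   # one fit, JSON record
jointsurv scenario  --gamma 0.4 --reps 300 --out scenario.csv
jointsurv reproduce --reps 1000 --out results/       # full 21-scenario experiment
```

`reproduce` writes the per-scenario summary table, the best-fit Z-test
SDs for both methods, and three figures: empirical power curves with
their Z-test fits, the test level (−log10 alpha) needed for 80% power as
a function of effect size, and histograms of the gamma estimates.  Every
table carries the config hash and master seed needed to regenerate it.
A YAML config file (see `RunConfig`) can override any default.

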