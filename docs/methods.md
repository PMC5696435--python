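# Methods

This note documents the models implemented in `bearipm`, the assumptions
behind them, the synthetic data the package generates, and the numerical
decisions made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Population model (count layer)

The population is structured into ten age–sex classes: cubs (C, age 0),
yearlings (Y, age 1), dependent young (D, age ≥ 2 still with their mother),
subadults (S, independent but immature) and adults (A), each split by sex.
Conventional age brackets for dependent young and subadults overlap in
calendar age; we key class on independence status first and age second,
which matches the weaning window (litter ages 2–3) used by the litter
model.

Writing `N_Xt` for the post-harvest abundance of class X in year t and
`N_Xt^BH` for its before-harvest counterpart, one year of dynamics is

```
N_Ct^BH   ~  Poisson(N_A♀,t−1 · Φ_A♀,t−1 · P_t−1 · L_t−1)        (total cubs)
N_C♂t^BH  ~  Binomial(N_Ct^BH, sr_t−1),   N_C♀t^BH = N_Ct^BH − N_C♂t^BH
N_Yt^BH   ~  Binomial(N_C,t−1, Φ_C,t−1)
N_Dt^BH   ~  Binomial(N_D,t−1, Φ_D(1−γ_D)) + Binomial(N_Y,t−1, Φ_Y)
N_St^BH   ~  Binomial(N_S,t−1, Φ_S(1−γ_S)) + Binomial(N_D,t−1, Φ_D γ_D)
N_At^BH   ~  Binomial(N_A,t−1, Φ_A)        + Binomial(N_S,t−1, Φ_S γ_S)
N_Xt      =  N_Xt^BH − H_Xt                                       (harvest)
```

per sex (Φ survival, γ transition, P adult-female reproduction probability,
L mean litter size, sr proportion of cubs male, H recorded harvest). The
`+` terms denote sums of independent Binomials, evaluated exactly by
convolution in `likelihoods.process_loglik`. The adult equation includes
the survival of last year's adults alongside maturing subadults; without
the adult-survival term the adult class could not persist.
Harvest is treated as data observed without error; a recorded harvest
exceeding the available abundance raises a data-inconsistency error rather
than being silently clipped. Repeated counts are
`C_Xt,k ~ Binomial(N_Xt, p)` with a single detection probability `p`
(constant across classes and years by default).

## Mark–recapture layer

Detection histories condition on first capture. The latent alive state
follows `z_t ~ Bernoulli(z_{t−1} φ_{t−1})`. Observation uses three
probabilities: live detection `p` (shared with the count survey by default,
since both use the same protocol; a flag splits them), dead recovery `p'`,
and reproduction detectability `p_r` for the `R` records of adult females
(`R ~ Bernoulli(ρ p_r z)`).

**Dead-recovery coherence.** Read literally, independent Bernoulli draws
for `y` (detection) and `r` (recovery) would allow the incoherent outcome
"dead, detected, not recovered". We instead model a single recovery event:
a newly dead bear is recovered with probability `p'`, which records
`y = r = 1` and terminates the history; otherwise it is never observed
again. With this rule the three one-interval outcomes
(seen alive, recovered dead, unseen) have probabilities
`φp`, `(1−φ)p'`, `φ(1−p) + (1−φ)(1−p')` that sum to one — the structure
real recovery record-keeping implies. The enumeration oracles in the test
suite certify the forward recursion under this rule for all histories of
length ≤ 4.

The latent alive state is marginalized analytically by a forward recursion
over {alive, dead-unrecovered} rather than sampled in MCMC. This is
distributionally identical and mixes far better than imputing thousands of
binary indicators.

## Litter layer

A recorded litter starts with `ℓ_1 ~ Poisson(λ)` truncated to ≥ 1 (a
recorded litter has at least one cub; the untruncated form is exposed for
validation). Each subsequent year the size thins as
`ℓ_t ~ Binomial(ℓ_{t−1}, φ_young)` with age-specific young survival (cub,
yearling, dependent). Weaning is impossible before litter age 2, certain
from age 4, and Bernoulli(`p_w`) at ages 2–3; every age 2–3 at which the
litter is observed alive contributes a weaning term (including the final
assessment of a right-censored record). The litter likelihood sums to one
over all complete trajectories from a fixed initial size (enumeration
oracle in the tests).

## Linking

Information flows between layers through deterministic aggregation:
class-averaged survival of marked subadults/adults feeds the count
transitions; young survival from the litter attrition model feeds the
C/Y/D transitions (sex-agnostic, since sex of dependent young is not
recorded); the population reproduction probability is the alive-weighted
mean of individual reproduction probabilities of adult females.

For the yearly litter size `L_t` the natural plug-in — the sample mean of
the initial sizes of litters recorded in year t — is provided by the
linking module, but the full model's count layer deliberately links to the
litter model's *population* mean litter size, the zero-truncated-Poisson
mean `λ/(1−e^{−λ})`, instead. The linked quantity is the average litter
size in the whole population; a handful of recorded litters per year is a
noisy estimate of it, and feeding that sample mean into the recruitment
Poisson as if exact makes the posterior ignore a real error component.
The effect is measurable: at desk scale the plug-in variant's 95%
intervals for the reproduction detectability covered the truth in only
12/20 simulated replicates, versus 18–20/20 with the model-based mean
(whose posterior width propagates the litter-sampling noise). At the
reference scale (ten litters per year) the two versions coincide closely.

When no marked animal of a class is alive in a year, the linked survival
node reverts to an independent draw from its prior — the only choice that
neither fabricates data nor crashes. The aggregation assumes
marked animals are a representative sample of the population; that
assumption is documented, not testable from these data.

In the simulation-study variant all individuals of a class share one rate,
so the alive-weighted averages reduce exactly to the class rates; the
general weighted form (weights = posterior alive probabilities from the
forward recursion) is exercised by the covariate-rich case-study variant.

## Priors and default parameters

| parameter | meaning | prior / default |
|---|---|---|
| p, p', p_r | detection, dead recovery, reproduction detectability | Uniform(0,1) |
| Φ, γ, ρ, φ_young, p_w | survival, transition, reproduction, young survival, weaning | Uniform(0,1) (per class-year where yearly) |
| sr_t | proportion of cubs male | Beta(a,b) moment-matched to mean 0.5238, variance 0.0771 (Kodiak literature values); Uniform(0,1) available |
| L_t (counts-only) | mean litter size | Uniform(0, 4) per year — litters of one to four cubs |
| λ | litter initiation rate | flat on (0, 30) |
| regression coefficients (case study) | logit/log-scale effects | Normal(0, 10) |
| random-effect scales | yearly heterogeneity | half-Normal(1); effects Normal(0, σ) |
| initial abundances | year-0 classes | discrete uniform on {0, …, N_cap}, N_cap = 10·max count + 200 |

A Uniform(0,1) prior on a mean litter size would be biologically absurd, so
`L_t` uses Uniform(0, 4); since `P_t · L_t` enters the density only as a
product, this choice affects nothing identifiable. The random-effect
distribution (Normal with a half-Normal(1) scale hyperprior) is this
package's choice of a weakly informative default.

## Synthetic data generator

The generator is the package's definition of the study conditions:

* **Rates.** One constant-in-time rate set per scenario, drawn uniformly
  from literature-style intervals for coastal brown bears (cub survival
  0.55–0.75, yearling 0.72–0.88, dependent/subadult 0.78–0.92, adult male
  0.85–0.93, adult female 0.90–0.96, weaning 0.30–0.60, maturation
  0.40–0.70, reproduction 0.15–0.45, mean litter size 1.8–2.8 cubs). The
  reproduction probability (falling back to adult female survival) is then
  calibrated so the deterministic growth rate matches the scenario trend —
  1.00 stable, 1.02 increasing, 0.98 decreasing; ±2%/yr is attainable
  within these intervals and realistic for managed brown bear populations.
* **Scales.** The reference design is 20 years of counts with four
  replicates per year, 1,000 marked individuals, 200 litters from 30
  reproducing females, detection 0.7, reproduction detectability 0.8,
  recovery 0.9. The `desk` scale (12 years, 300 individuals, 80 litters,
  initial abundances reduced 40%) is the default problem size for
  interactive work and for the acceptance script.
* **Harvest** is Binomial per class with rates {C: 0, Y: 0, D: 0.01,
  S: 0.04/0.02, A: 0.08/0.03 (male/female)} — cub/yearling harvest is
  typically zero and adult males carry the heaviest pressure.
* **Marked animals** enter as subadults or adults in staggered years,
  75% female (collaring programmes deliberately bias toward adult females);
  ageing is deterministic, so a marked bear's class is known.
* **Litters** use a zero-truncated Poisson whose rate solves
  `λ/(1−e^{−λ}) = L`, so the realized mean litter size equals the scenario
  parameter that also drives cub recruitment — keeping the two layers
  mutually coherent.

What the generator does **not** emulate: individual heterogeneity beyond
class and sex, movement and spatial sampling, age misclassification in
counts, density dependence, environmental stochasticity in rates, tag loss,
or incomplete harvest reporting. Tests passing on these simulations
therefore certify the estimator under a correctly specified model — they do
not certify robustness to the above features of real data.

## Inference

Posterior sampling is Metropolis-within-Gibbs, specialized per variant:

* **Latent abundances** are updated by compiled single-site integer
  random-walk proposals. The two Binomial components of the dependent,
  subadult and adult recruitment sums are kept as explicit latent splits:
  their marginal law is exactly the convolution model (verified by an
  enumeration test), every process term becomes a plain Binomial/Poisson
  pmf, and each pair also gets a sum-preserving exchange move.
* **Conjugate draws** wherever the structure allows: single-Binomial
  survival rates, the sex ratio (Beta), detection in the counts-only model
  (Beta), weaning (Beta), and truncated-Gamma draws for `P_t` and `L_t`.
* **Slice sampling** (stepping-out/shrinkage) for the remaining scalars,
  with conditionals reduced to sufficient statistics so an evaluation costs
  one compiled kernel call plus O(1) arithmetic.
* **Detection–abundance rescaling move.** The repeated-count likelihood has
  a ridge: scaling every abundance by `p/p'` compensates a change of
  detection. Single-site updates cross it extremely slowly, which shows up
  as apparently precise but badly placed abundance posteriors. A joint move
  proposes `p'` on the logit scale and every latent as a randomized
  rounding of `N·p/p'` (rounding noise sd 0.15 — even one-individual noise
  in the tightly coupled year-to-year Binomials would reject every
  proposal). Acceptance is ~25–30% at desk scale. This move is what makes
  the counts-only variant converge; see "On the coverage comparison".
* **Initialization.** Latent abundances start at max count / 0.5, repaired
  backward so every Binomial has enough trials; probabilities start at
  mid-range values. Chains that cannot find a finite-density start are
  re-initialized with inflated abundances a bounded number of times, then
  fail loudly.
* **Protocols.** `desk`: 2 chains × 5,000 burn-in + 5,000 iterations.
  `paper`: 3 chains × 50,000 + 50,000, thinned by 4 — the reference
  protocol, available as a named preset but far beyond interactive budgets.
  Convergence is monitored with the classic potential scale reduction
  factor (non-split, non-rank-normalized, matching the hand-checkable
  closed form; all-constant chains return a NaN sentinel with a warning).
  Runs with any monitored R̂ ≥ 1.1 are flagged in reports, never dropped.

## Evaluation harness

`run_comparison_study` simulates a scenario, fits the full model and the
counts-only model to the same count + harvest tables, and scores per
class-year abundance: 95% equal-tailed credible intervals, coverage of the
simulated truth, bias and RMSE, pooled across class-years (per-class and
per-scenario breakdowns are emitted alongside). `scripts/acceptance.py`
runs this end to end at desk scale — three trends, one seed each, 12 years
× 10 classes × 3 scenarios = 360 scored class-years — and writes the two
pooled coverage percentages.

### On the coverage comparison

Integrated population models are often motivated by a dramatic contrast:
near-nominal interval coverage for the IPM against a counts-only fit whose
intervals contain the truth only a few percent of the time. Our harness
reproduces the first half: the integrated model's 95% intervals contain the
true class-year abundances ≈ 95% of the time at desk scale. It does **not**
reproduce a counts-only collapse, for a structural reason worth stating
plainly: the counts-only variant here is fitted to data simulated from
exactly the generative process it assumes, and a convergent sampler then
yields close-to-calibrated credible intervals *by construction* — weak data
widen the intervals rather than misplace them (counts-only intervals are
indeed wider: larger RMSE at equal coverage).

A dramatic counts-only failure is, however, easy to produce *as a sampler
artifact*: without the rescaling move and with short chains, the detection
probability barely leaves its initialization, every abundance is biased by
the corresponding factor, and the intervals — tight around the wrong value
— miss almost everywhere while looking precise. Off-the-shelf Gibbs
samplers that update discrete abundances one node at a time are exactly in
this regime on this model. We therefore treat "counts-only covered only a
few percent" as a caution about convergence diagnostics in weakly
identified N-mixture models, not as a property of the correctly computed
posterior, and we keep the convergent sampler. The acceptance harness
reports what the convergent fit produces.

## Case-study (reduced) variant

With no usable count series, the reduced model joins the CMR and litter
layers directly, with the retained covariate structure: adult/subadult
survival ~ age + age² + sex + salmon biomass + subadult flag; reproduction
~ age + salmon + age at first reproduction + dependent-young flag; initial
litter size (log link) ~ mother's age + age at first reproduction + salmon;
young survival ~ litter age + litter age² + litter size + mother's age +
salmon; weaning ~ litter age; each with a yearly random effect. Continuous
covariates are z-scored (sampler stability; comparable slopes). The
dependent-young flag records young carried into the year, before any new
reproduction — the convention that makes "females with dependent young do
not reproduce" estimable. Salmon biomass enters survival at the interval's
start year; a one-year lag, if preferred, is a covariate-table choice, not
a code change. Litter sizes assessed shortly
before den entrance are post-early-mortality sizes, which depresses
apparent litter size relative to den-emergence counts; derived annual
litter sizes inherit that timing.

Identifiability caveat: with no count layer, the reproduction intercept and
`p_r` enter the likelihood only through their product, so only the product
(and the covariate effects) are identified; recovery tests assert
identified quantities. In the full model the count layer separates them.
The deposited historical tables are not distributed with the package; the
pipeline is validated by parameter recovery on synthetic stand-ins
(`generate_synthetic_kodiak`, and the packaged ten-bear fixture) with
known effect structures.

## Known limitations

* No density dependence, spatial structure, movement or genetic effects.
* Detection constant across classes and years (removable by design, not
  exposed as a switch).
* Single-population, single-area; the four historical study areas are not
  modeled separately.
* The paper-scale MCMC protocol is provided but not exercised by the test
  suite; desk-scale chains are validated by R̂ and by parameter-recovery
  checks instead.
* Incomplete harvest reporting is out of scope; harvest is data.
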