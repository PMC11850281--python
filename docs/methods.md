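# Methods

## Scores

**HDDS.** The household dietary diversity score counts distinct food
groups consumed over a 7-day recall. Of the 12 standard groups, the three
low-nutrient ones (spices/condiments/beverages, sugar/sweets, oils/fats)
are excluded everywhere, so all scores range 0–9. Source-specific
components (own production, market purchase, other) count groups with at
least one record of that source; a group reached through two sources
counts once in the total, so `max(components) ≤ HDDS ≤ sum(components)`.

**FPD.** Farm production diversity is measured two ways: the number of
distinct species produced (non-food cash crops count — they are species
produced, even though they feed no food group) and the number of distinct
nutritious food groups produced. Livestock species map to several groups
(cattle → meat and milk; chicken → meat and eggs), read as the union of
what the animal can supply; consequently food-group FPD can exceed the
species count for livestock keepers. A config-level alternative that
drops cash crops from the species count is available via a custom
taxonomy (cash-crop rows removed).

**Subsistence.** The own-production share of total consumption value;
households strictly above 50% are classed subsistence. The comparison is
strict, so a household at exactly one half is not subsistence.
Household-waves with zero total recorded value have an undefined share:
they are flagged missing, logged, and excluded from share-based analyses
rather than imputed.

**LPD.** Local production diversity at village/town/district scale is the
union of nutritious food groups produced by the *sampled* farm households
of the unit in a wave — a lower bound on true local diversity. Village
singletons (≤1 sampled farm household in that village-wave) are marked
invalid because farm- and village-level diversity would coincide; the
rule is applied per wave, since sampling varies by wave, and does not
propagate to town/district aggregates, where identity is not at issue.
Households with missing village classification are excluded from
village-scale estimation only.

## Estimators

Pooled OLS on household panels is biased when time-invariant household
traits (ability, land quality, food preferences) drive both production
diversity and diets. Two devices absorb them:

* **CRE (Mundlak).** The pooled regression is augmented with household
  means, over each household's observed waves, of the focal regressor,
  the interaction term and every time-varying covariate. Time-invariant
  covariates (head characteristics, landholding, distance) stay
  estimable. Country dummies enter pooled multi-country models only;
  wave dummies always.
* **FE (within).** Outcome and regressors demeaned within household;
  time-invariant regressors are annihilated and dropped with a log entry.

**Exact FE↔CRE equivalence.** On balanced panels the equivalence of the
coefficients on time-varying regressors is the classical Mundlak
identity. On unbalanced panels it additionally requires the household
means of the *wave dummies* among the Mundlak terms (within-deviations
are orthogonal to every household-constant column; wave dummies are not
household-constant unless their means are partialled out too). The
design builder therefore adds wave-dummy means in CRE mode and prunes
them silently when they are constant (the balanced case). Pruning is
restricted to automatically added columns (Mundlak means, dummies);
collinearity among user-specified regressors raises an error instead of
silently dropping.

**Inference.** All covariances are CR1 cluster-robust sandwiches,
`c · (X'X)⁻¹ (Σ_g s_g s_g') (X'X)⁻¹` with `c = G/(G−1)·(N−1)/(N−K)`,
clustered on the household by default (the level at which observations
repeat); the cluster column is configurable. With singleton clusters
CR1 reduces exactly to HC1. Confidence intervals use the normal
approximation (±1.96·SE). For the FE estimator the degrees-of-freedom
correction counts the absorbed household intercepts. Clustering level
and dof treatment are explicit, documented choices of this package.

**Poisson.** Because the HDDS is a count, a log-link Poisson quasi-ML
variant is provided: Newton–Raphson with analytic score and Hessian,
step halving, convergence when the maximum absolute score falls below
1e-8 (100-iteration cap), and the same CR1 sandwich — valid under
arbitrary dispersion. An all-zero outcome is rejected (the mean is not
representable with a finite intercept).

**Marginal effects.** For the FPD × distance interaction,
`effect(d) = β₁ + β₂ d` with delta-method SE
`√(v₁₁ + d² v₂₂ + 2 d v₁₂)` — exact for a linear interaction. The default
reporting grid is 0–100 km in 10-km steps.

**Attrition weights.** The attrition correction is inverse-probability
weighting: for each country and wave t ≥ 2 a logistic model of retention
(among households retained at t−1) on first-wave covariates is fitted by
Newton–Raphson; the weight of an observed household-wave is the inverse
cumulative predicted retention probability, normalized to mean 1 within
country-wave (waves are country-specific, so country-wave is the wave
unit). Separation is detected (diverging linear predictor) and raised,
not papered over. This is a standard selection-on-baseline-observables
correction; it cannot remove selection on unobservables beyond what the
baseline covariates proxy.

## Synthetic data

The generator emulates the statistical structure the estimators assume,
not any particular country's survey:

* **Design.** 6 countries × 14 districts × 10 towns × 12 villages × 9
  households ≈ 90,700 households over 10,080 villages; waves per country
  (3, 4, 2, 4, 5, 7). Villages draw distance-to-urban-centre from
  Gamma(2, 15.5) (mean 31 km). 78% of households farm, giving ≈7 sampled
  farm households per village.
* **Heterogeneity and confounding.** A household effect
  c_i ~ N(0, 0.8²) enters the outcome additively and shifts the log-mean
  of the species count by κ·c_i (κ = 0.25, with a lognormal mean
  correction so the pooled species mean stays on target). This is the
  simplest channel that makes pooled OLS biased and CRE/FE necessary.
* **Production.** Species count per farm-wave is 1 + NegBin(mean 4.55,
  size 3.2) — pooled mean 5.55, overdispersed, floor of one species per
  farm; species drawn without replacement with prevalence weights
  (weighted Gumbel top-k), cash crops among them.
* **Consumption (structural mode).** Produced nutritious groups are
  consumed from own production with probability 0.55; market purchase of
  each group follows a logit in a wealth index, standardized distance and
  (weakly) c_i around group-specific base rates; "other" sources are rare
  (p = 0.071). Record values are lognormal; own-production values are
  scaled so the pooled own-value share centres on 33.14% — the target
  mean conditional share is set to `target / f`, where `f` is the
  realized fraction of household-waves with own-production records, which
  centres the pooled mean by construction.
* **Outcome modes.** `structural` yields an integer HDDS through the
  mechanism above and is used for descriptive calibration. `linear`
  additionally writes a continuous latent diet index that follows the
  estimating equation exactly (α = 4, configurable β on either FPD
  metric, interaction on the groups metric × distance, covariate effects
  δ, c_i, ε ~ N(0, 1.2²)); coefficient-recovery experiments use it
  because integer censoring of a 0–9 count would attenuate the recovered
  coefficients.
* **Covariates.** Binary assets/employment follow sticky Markov chains
  (persistence 0.88); weather shocks are i.i.d. per wave (p = 0.2); head
  characteristics and landholding are fixed at baseline. Head age is
  deliberately frozen at baseline: a linearly aging head is collinear
  with wave dummies under the within transform. Landholding is lognormal
  (μ = −0.2, σ = 1), correlated 0.3 with c_i, giving ≈81% of farms below
  2 ha.
* **Attrition.** From each wave after the first, households drop out
  permanently with probability logistic in baseline covariates
  (optionally in c_i, for non-ignorable scenarios in tests); retention
  indicators are kept for IPW. Default per-wave base rate 0.06.
* **Reproducibility.** One root seed; child streams per table derive
  from fixed `SeedSequence` spawn keys (geography 0, households 1,
  production 2, consumption 3, attrition 4, latent 5), so adding a table
  never perturbs another. Identical config + seed reproduces the panel
  bit for bit.

Calibration targets (pooled HDDS mean, species mean, own-value share,
distance, farms per village, farm-size share) were fixed once against
reference descriptive statistics typical of these surveys and are
verified by the test suite; reported livestock/crop/total food-group
breakdowns in such descriptives can be internally inconsistent
(a component exceeding the total) and are not calibration targets. What
passing these checks shows is that the pipeline's mechanics are correct
under a data-generating process with the assumed structure — not that
the generator captures seasonality, price variation, measurement error
or intra-household allocation, none of which are modelled.

## Numerical choices and degenerate inputs

* OLS via QR; coefficients agree with the normal-equations solution to
  1e-10 on full-rank problems; numerically rank-deficient designs raise.
* Mundlak means are computed over each household's observed waves
  (unbalanced panels included).
* Reference categories for dummies: alphabetically/numerically first
  country and wave, so outputs are bit-for-bit reproducible.
* Weighted fits require strictly positive weights; weights are used in
  estimation and in the sandwich scores.
* The "exclude missing/outliers" step of survey practice is implemented
  as: rows with missing model variables dropped with a logged count, and
  an optional country-wave [1st, 99th]-percentile trim of total
  consumption value (`trim_outliers`, off by default; inert on clean
  synthetic data).
* Problem sizes in tests: recovery runs use ~2,880 households × 3 waves
  × 5 seeds; the bias comparison 50 replicates of ~2,016 households; CI
  coverage 200 replicates of ~288 households; calibration one full
  default panel. These sizes give Monte-Carlo errors well inside the
  asserted tolerances.

## Known limitations

* The interchange format is a single canonical CSV schema; harmonizing
  real, heterogeneous national survey files is out of scope.
* No survey weights, calorie/quantity accounting, seasonality, or
  individual-level intake.
* The attrition correction is the package's concrete stand-in for an
  unspecified correction; alternative corrections (e.g. Heckman-type)
  are not implemented.
* Spatial aggregation follows administrative nesting only; market-shed
  definitions and remote-sensing-based diversity are out of scope.
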