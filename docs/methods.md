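# Methods

## Study design and estimand

The package implements a pairwise-year comparison of preterm-birth odds on
live-birth registry microdata. Births of two calendar years are stacked; the
period indicator *z* marks the later year and the outcome *y* marks preterm
birth, defined as 22–36 completed weeks of gestation (term ≥ 37 weeks; the
threshold is configurable via `preterm_upper`). Births below 22 completed
weeks are excluded everywhere; multiple pregnancies are retained. Records
with unknown gestational age have no defined outcome: they stay in
descriptive denominators (the national descriptive tables carry a
"not stated" row against the all-births denominator) but never enter model
fits.

The reported quantity is the year odds ratio exp(β_z) from a weighted
logistic regression of *y* on *z* and covariates, where the weights are raw
inverse-probability-of-treatment weights built from a propensity model
*e(x) = P(z = 1 | x)*. With a homogeneous period effect and a correctly
specified outcome model this estimates the covariate-conditional year
effect; the package also exposes an exact enumeration of the marginal
(standardised) odds ratio for synthetic data, and the two differ only
through non-collapsibility of the odds ratio (≈ 0.1% at effect sizes near
1.04 and an 11% outcome prevalence).

## Pipeline stages and numerical choices

**Recoding.** Raw registry codes map onto closed category sets mirroring the
national descriptive table: maternal age <19 / 19–34 / >34, schooling 0–7 /
8–11 / 12+ years, antenatal visits none / 1–3 / 4–6 / 7+, parity
primiparous/multiparous (primiparous ⇔ zero prior deliveries), plus
race/colour, marital status, pregnancy type, delivery mode and newborn sex.
Recoding is total: every raw value lands in a category or "unknown", and
declared missing codes never coerce silently into valid categories.

**Design matrices.** Categorical covariates are one-hot encoded against the
published reference levels (age 19–34, female, white, 12+ schooling,
married/cohabiting, singleton, no antenatal visits, vaginal, primiparous).
Rows missing a modelled covariate are dropped (complete-case, counts
reported) except that newborn sex keeps an explicit "unknown" indicator, the
one unknown level the published regression reports. Columns constant across
the remaining rows are dropped with a warning.

**Logistic fits.** Maximum likelihood via iteratively reweighted least
squares, with weights entering as relative frequency weights. Convergence:
relative log-likelihood change below 1e−8 on three consecutive iterations
(the extra Newton steps exploit quadratic convergence to pin the optimum to
near machine precision, so small-table odds ratios agree with closed-form
cross-product ratios to 1e−8), or a score-norm exit two orders stricter.
Safeguards: fitted probabilities are clipped at 1e−10 inside the information
matrix so perfectly predicted rare cells cannot singularise it; Newton steps
are capped at 8 in the max norm with step-halving on likelihood decreases;
max 100 iterations; non-convergence and apparent separation (any coefficient
beyond 15 in absolute value) are flagged, never silently returned.

**Covariance.** Default is the inverse observed information ("model-based
Wald", matching the very narrow intervals a multi-million-record registry
yields). Because raw IPW weights sum to roughly twice the sample size, the
frequency-weight information overstates precision by about √2; a robust
sandwich estimator (bread × Σ of squared per-unit *weighted* scores × bread)
is available via `variance="robust"` and is what the calibration studies
use. The sandwich ignores propensity-estimation uncertainty, which makes it
mildly conservative here.

**Propensity scores and trimming.** Scores are clipped to [1e−6, 1 − 1e−6]
before weighting so inverse weights stay finite. Trimming removes records
strictly outside the empirical [Q(f), Q(1−f)] interval of the pooled
(both-periods) score vector, with f = 0.10 per tail by default and the
median-unbiased quantile estimate; ties at the cut are retained. On distinct
scores this keeps 80% of the records, reproducing the common-support
arithmetic of the source design. Pooled (rather than per-group) quantiles
were chosen because they reproduce that 80% retention exactly.

**Diagnostics.** Standardized mean differences per design column,
(m₁ − m₀)/√((v₀ + v₁)/2) with weighted moments when weights are supplied,
and Gaussian-KDE score-overlap curves (Silverman bandwidth, 512-point grid
on [0, 1]; degenerate groups are flagged rather than estimated).

**Orchestration.** `run_pairwise_psw` iterates year pairs × regions
(default pairs 2017–2018, 2018–2019, 2019–2020, 2019–2021 — both pandemic
years against the 2019 baseline). Regional cells re-estimate the propensity
model within the region, the faithful reading of a stratified analysis
(reusing national scores is possible by running the stages manually).
Per-cell failures are recorded in the summary and skipped; the chain has no
hidden state, so composition equals the manual stage sequence bit for bit.

## The synthetic registry generator

The generator emulates exactly what the estimator needs to be tested
against, and no more:

* **Covariates** are drawn independently from the published 2019 national
  marginals ("not stated" mass removed and renormalised). Real registries
  have correlated covariates; independence is sufficient to create
  confounding and test balance, and a joint tilt can be injected by editing
  the marginals. Region is an independent label with plausible national
  shares; no spatial structure is simulated.
* **Period assignment** is Bernoulli with logit equal to a covariate score
  tilting later-year membership toward higher-risk profiles (older mothers,
  multiparity, caesarean delivery, few antenatal visits, lower schooling,
  +0.05 to +0.30 per level), intercept calibrated by enumeration so both
  periods are equally sized. Under a null period effect this mix shift
  biases the crude odds ratio to ≈ 1.08 — material confounding for the
  estimator to remove.
* **Outcome** is Bernoulli with logit = intercept + covariate effects +
  period effect × z. Covariate effects are the logs of the published
  2019–2020 adjusted odds ratios (twin 3.44, 7+ antenatal visits 0.70, male
  1.39, …); the intercept is calibrated by enumeration to an 11.2% marginal
  preterm share. The default period effect is ln(1.04), the published
  2019–2020 year effect.
* **Gestational age** is drawn consistently with the outcome (22–36 weeks
  for preterm, skewed toward late preterm; 37–42 for term) and
  **birthweight** from two normals (2400 ± 600 g preterm, 3300 ± 450 g term,
  truncated at 300 g). Birthweight is therefore a *descendant of the
  outcome*, not a confounder: adjusting for it in the synthetic outcome
  model attenuates the period coefficient, so the calibration harness fits
  the birthweight-free specification (correct for this data-generating
  process), while the real-data defaults keep birthweight in both models,
  matching the published covariate set.
* **Missingness** is applied last, independently per field, at
  registry-like rates (≈ 0.1–1.3%). It is missing-completely-at-random;
  informative missingness is not emulated, so the tests say nothing about
  complete-case bias on real data.
* A multi-year companion (`simulate_registry`) draws each year
  independently with per-year true effects for pipeline drivers; cross-year
  confounding is only present in the pairwise generator, which is what all
  confounding tests use.

Because the covariate space is finite (17,280 cells), the population crude
odds ratio, marginal odds ratio and calibration targets are computed by
exact enumeration; Monte-Carlo versions (`true_marginal_or`) are
deterministic given the configured seed. Identical (config, seed) yields
bit-identical output files.

## Calibration studies and problem sizes

The estimator's statistical properties are checked on the confounded
generator at n_per_year = 20,000 — large enough that per-replicate
Monte-Carlo error (SD of the log year-OR ≈ 0.04) resolves the biases at
stake, small enough that a hundred replicates run in about a minute:

* **Null calibration** (100 seeds, period effect 0): the robust-variance
  95% CI should cover 1.0 at its nominal rate while the mean crude OR sits
  several Monte-Carlo SEs above 1.
* **Effect recovery** (50 seeds, period effect ln(1.04)): the mean PSW
  estimate should lie within two Monte-Carlo SEs of the enumeration-oracle
  odds ratio. This is a 2-sigma check by construction, so roughly one seed
  batch in twenty fails by chance even for an unbiased estimator.
* **Balance**: on every confounded fixture the maximum absolute SMD must
  shrink after weighting.

## Known limitations

* The published national coefficient tables come from ~4.2-million-record
  stacks; they are not reproducible at desk scale and are used only as
  generator inputs (marginals, coefficient values), never as test targets.
* One published descriptive-table cell (2021 preterm share) disagrees with
  its own printed counts by one unit in the last digit, and a handful of
  cells are internally inconsistent; `reference.TABLE1_ERRATA` lists them
  and the tests check all remaining cells.
* Native registry binary formats are out of scope; the reader consumes
  delimited text exports with a configurable column mapping and missing
  codes.
* No matching, stratification, doubly-robust or stabilised-weight
  estimators; no imputation of missing covariates; odds ratios are
  associational — no causal identification is claimed beyond the weighting
  adjustment itself.
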