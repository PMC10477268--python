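# pretermpsw

Propensity-score-weighted analysis of preterm-birth odds across years of
live-birth registry microdata, with a synthetic registry generator that makes
every stage of the analysis verifiable at desk scale.

The package is aimed at perinatal epidemiologists and biostatisticians who
want to compare the odds of preterm birth (22–36 completed weeks of
gestation) between calendar years of a national birth registry — for example
pandemic years against a pre-pandemic baseline — while adjusting for shifts
in the maternal and obstetric case mix.

## The method

Two years of individual-level records are stacked with a period indicator
*z* (0 = earlier year, 1 = later year) and a preterm outcome *y*. The
analysis is the standard quasi-experimental inverse-probability-weighting
recipe:

1. **Propensity model.** A logistic regression of *z* on maternal and
   obstetric covariates *x* (age band, race/colour, schooling band, parity,
   mode of delivery, marital status, antenatal-visit band, birthweight)
   yields the propensity score *e(x) = P(z = 1 | x)*.
2. **Common-support trimming.** Records in the tails of the pooled score
   distribution are pruned — by default everything strictly outside the
   empirical 10% and 90% quantiles, retaining 80% of the records.
3. **Weights.** Later-year records are weighted by *w = 1/e(x)*, earlier-year
   records by *w = 1/(1 − e(x))* (raw IPW, no normalisation).
4. **Outcome model.** A weighted logistic regression of *y* on *z* and the
   covariates reports the year odds ratio OR = exp(β_z) with a 95% CI —
   model-based Wald by default, robust sandwich by flag.

Logistic fits use iteratively reweighted least squares written for exactness
and speed on aggregated tables (on any 2×2 table the fitted OR equals the
cross-product ratio to better than 1e−8); covariate balance is diagnosed by
standardized mean differences and score-overlap KDE curves.

The synthetic generator draws the covariates from the published 2019
national registry marginals, assigns the period with covariate-dependent
probability (confounding) and the outcome from a logistic model with a
configurable true period effect, so crude-vs-adjusted behaviour, CI coverage
and effect recovery can all be checked against exact enumeration oracles
over the finite covariate space.

## Worked example

```python
import math
from pretermpsw import synthetic as syn, registry_io as rio, pipeline

cfg = syn.default_config(n_per_year=20_000, period_effect=math.log(1.04), seed=1)
records = rio.recode(syn.simulate_births(cfg))
result = pipeline.run_pairwise_psw(records, pairs=((2019, 2020),))
print(result.summary[["pair", "n_before", "n_after", "year_or", "ci_low", "ci_high"]])
```

prints

```
        pair  n_before  n_after   year_or    ci_low   ci_high
0  2019-2020     39476    30673  1.046177  0.980243  1.116545
```

39,476 eligible births with known gestational age enter the 2019–2020 cell;
trimming keeps 30,673 (80% of the scored records), and the weighted
regression estimates a year OR of 1.05 [0.98–1.12] against a true simulated
effect of 1.04. The same chain is available from the shell:

```sh
psw simulate --out births.csv --seed 42
psw run --input births.csv --pairs 2019:2020 --out results/
psw describe --input births.csv --out table.csv
```

Over 50 seeded replicates of the confounded generator
(`python analysis/04_calibration.py`) the behaviour is:

```
null: PSW CI covered 1.0 in 47/50 replicates; mean PSW OR 1.0061, mean crude OR 1.0874
recovery: mean PSW OR 1.0397 (MC SE of log 0.0056) vs enumeration oracle 1.0391; mean crude OR 1.1269
```

i.e. the crude odds ratio is biased upward by the confounded case mix while
the weighted estimator removes the bias and recovers the injected effect.

The numbered drivers under `analysis/` run the full study shape on synthetic
data: `01_simulate_registry.py` (five-year registry), `02_descriptives.py`
(category shares per year, caesarean rate by gestational-age band, caesarean
OR among preterm births), `03_pairwise_psw.py` (four year pairs × national +
five macro-regions) and `04_calibration.py`; their tables land in
`results/`.

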