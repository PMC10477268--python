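"""Replication harness for statistical calibration of the PSW estimator.

Runs the full chain (simulate -> recode -> stack -> propensity -> trim ->
weight -> weighted outcome regression) over many seeded replicates of the
synthetic registry, recording the crude and PSW-adjusted year odds ratios.
Used to check two properties of the estimator under the generator's
confounded conditions:

* **null calibration** — with a zero true period effect, the PSW 95% CI
  should cover 1.0 at its nominal rate while the crude odds ratio is biased
  away from 1;
* **effect recovery** — an injected period log-odds effect should be
  recovered, on average, to within Monte-Carlo error of the enumeration
  oracle.

Confidence intervals here use the robust sandwich variance: with raw
inverse-probability weights the weight total is roughly twice the sample
size, so model-based (frequency-weight) Wald intervals are too narrow by
about sqrt(2) and cannot attain nominal coverage.

The harness fits the propensity and outcome models without birthweight.  In
the generator birthweight is drawn *from* the preterm outcome (it is a
descendant of y, not a confounder), so conditioning on it attenuates the
period coefficient; excluding it is the correctly specified model for the
synthetic data-generating process.  On real registry data the package's
default covariate sets keep birthweight, matching the published model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import psw
from .pipeline import PSWConfig, build_stacked, run_cell
from .registry_io import recode
from .synthetic import SyntheticConfig, default_config, simulate_births

#: covariate sets correctly specified for the generator (no birthweight)
PS_COVARIATES: tuple[str, ...] = tuple(
    c for c in psw.DEFAULT_PS_COVARIATES if c != "birthweight"
)
OUTCOME_COVARIATES: tuple[str, ...] = tuple(
    c for c in psw.DEFAULT_OUTCOME_COVARIATES if c != "birthweight"
)


@dataclass
class Replicate:
    seed: int
    psw_or: float
    ci_low: float
    ci_high: float
    crude_or: float
    converged: bool


def crude_or_from_stacked(data: pd.DataFrame) -> float:
    """Cross-product odds ratio of the 2x2 (z, y) table."""
    tab = pd.crosstab(data["z"], data["y"].astype(int))
    return float((tab.loc[1, 1] * tab.loc[0, 0]) / (tab.loc[1, 0] * tab.loc[0, 1]))


def run_replicate(
    seed: int,
    n_per_year: int = 20_000,
    period_effect: float = 0.0,
    variance: str = "robust",
    trim_fraction: float = 0.10,
    config: SyntheticConfig | None = None,
) -> Replicate:
    """One seeded end-to-end replicate under the confounded conditions."""
    if config is None:
        cfg = default_config(n_per_year=n_per_year, period_effect=period_effect, seed=seed)
    else:
        cfg = default_config(
            **{
                **{f: getattr(config, f) for f in ("covariate_marginals", "outcome_coefs", "confounding_coefs", "missing_rates", "years")},
                "n_per_year": n_per_year,
                "period_effect": period_effect,
                "seed": seed,
            }
        )
    records = recode(simulate_births(cfg))
    stacked = build_stacked(records, *cfg.years)
    cell = run_cell(
        stacked,
        PSWConfig(
            ps_covariates=PS_COVARIATES,
            outcome_covariates=OUTCOME_COVARIATES,
            variance=variance,
            trim_fraction=trim_fraction,
        ),
    )
    ci_low, ci_high = cell.fit.year_ci()
    return Replicate(
        seed=seed,
        psw_or=cell.fit.year_or,
        ci_low=ci_low,
        ci_high=ci_high,
        crude_or=crude_or_from_stacked(stacked.data),
        converged=cell.fit.fit.converged,
    )


def calibration_study(
    n_reps: int,
    n_per_year: int = 20_000,
    period_effect: float = 0.0,
    base_seed: int = 0,
    variance: str = "robust",
) -> pd.DataFrame:
    """Seeded replicates ``base_seed .. base_seed + n_reps - 1`` as a table."""
    rows = [
        run_replicate(
            seed=base_seed + i,
            n_per_year=n_per_year,
            period_effect=period_effect,
            variance=variance,
        )
        for i in range(n_reps)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def summarize(study: pd.DataFrame, true_or: float = 1.0) -> dict[str, float]:
    """Coverage and bias summaries of a calibration study.

    ``coverage`` counts replicates whose CI contains ``true_or``;
    ``*_se`` are Monte-Carlo standard errors of the mean log odds ratios.
    """
    log_psw = np.log(study["psw_or"].to_numpy())
    log_crude = np.log(study["crude_or"].to_numpy())
    n = len(study)
    covered = ((study["ci_low"] <= true_or) & (study["ci_high"] >= true_or)).sum()
    return {
        "n_reps": n,
        "coverage": float(covered) / n,
        "n_covered": int(covered),
        "mean_log_psw": float(log_psw.mean()),
        "se_log_psw": float(log_psw.std(ddof=1) / math.sqrt(n)),
        "mean_psw_or": float(np.exp(log_psw.mean())),
        "mean_log_crude": float(log_crude.mean()),
        "se_log_crude": float(log_crude.std(ddof=1) / math.sqrt(n)),
        "mean_crude_or": float(np.exp(log_crude.mean())),
    }
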