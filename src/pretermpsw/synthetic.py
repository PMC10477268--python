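"""Synthetic live-birth registry generator with known ground truth.

The generator emulates the structure of national registry microdata at desk
scale: categorical maternal/obstetric covariates drawn from the published 2019
marginals, a binary "later year" period indicator whose assignment probability
depends on covariates (confounding), and a preterm outcome drawn from a
logistic model over the same covariates plus a configurable true period effect
on the log-odds.  Because the data-generating process is fully known and the
covariate space is finite, every downstream stage — propensity estimation,
trimming, weighting, the weighted outcome regression — can be validated
against exact enumeration oracles.

Default conditions
------------------
* covariate marginals: the 2019 column of the national descriptive table,
  "not stated" mass removed and renormalised (missingness is applied last,
  independently per field, at registry-like rates of ~0.1-1.3%);
* outcome coefficients: the log adjusted odds ratios of the published
  2019-2020 regression column, intercept calibrated by enumeration so the
  marginal preterm share is ~11%;
* period effect: ln(1.04), the published 2019-2020 year effect;
* confounding: later-year membership tilted toward higher-risk profiles
  (older mothers, multiparity, caesarean, few antenatal visits, low
  schooling), intercept calibrated so both periods are equally sized.

Gestational age is drawn consistently with the outcome (22-36 completed weeks
for preterm draws, 37-42 for term draws) and birthweight from two normal
distributions (preterm vs term) truncated at 300 g, so weight is associated
with the outcome without entering the structural model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .reference import REGION_SHARES, table1_marginals
from .registry_io import (
    DELIVERY_CODES,
    MARITAL_CODES,
    PREGNANCY_CODES,
    RACE_CODES,
    RAW_FIELDS,
    SEX_CODES,
)

#: simulated covariates, in generator order
COVARIATES: tuple[str, ...] = (
    "age_cat",
    "parity_cat",
    "delivery_cat",
    "sex_cat",
    "race_cat",
    "schooling_cat",
    "marital_cat",
    "pregnancy_cat",
    "anc_cat",
)

#: log adjusted odds ratios of the published 2019-2020 regression column
DEFAULT_OUTCOME_COEFS: dict[str, dict[str, float]] = {
    "age_cat": {"<19": math.log(1.19), ">34": math.log(1.26)},
    "parity_cat": {"multiparous": math.log(1.19)},
    "delivery_cat": {"caesarean": math.log(1.09)},
    "sex_cat": {"male": math.log(1.39)},
    "race_cat": {
        "black": math.log(0.90),
        "asian": math.log(0.99),
        "brown": math.log(1.03),
        "indigenous": math.log(1.50),
    },
    "schooling_cat": {"8-11": math.log(1.05), "0-7": math.log(1.15)},
    "marital_cat": {"single": math.log(0.93), "widow": math.log(0.96)},
    "pregnancy_cat": {"twin": math.log(3.44), "triplet+": math.log(4.56)},
    "anc_cat": {"1-3": math.log(1.50), "4-6": math.log(1.28), "7+": math.log(0.70)},
}

#: log-odds tilts of later-year membership toward higher-risk profiles
DEFAULT_CONFOUNDING_COEFS: dict[str, dict[str, float]] = {
    "age_cat": {"<19": 0.15, ">34": 0.30},
    "parity_cat": {"multiparous": 0.25},
    "delivery_cat": {"caesarean": 0.25},
    "race_cat": {"brown": 0.05, "indigenous": 0.20},
    "schooling_cat": {"8-11": 0.05, "0-7": 0.20},
    "pregnancy_cat": {"twin": 0.10},
    "anc_cat": {"1-3": 0.30, "4-6": 0.10, "7+": -0.20},
}

#: registry-like "not stated" rates per raw field
DEFAULT_MISSING_RATES: dict[str, float] = {
    "gestational_age": 0.013,
    "race": 0.010,
    "schooling_years": 0.008,
    "marital_status": 0.008,
    "anc_visits": 0.004,
    "pregnancy_type": 0.0008,
    "delivery_mode": 0.0007,
    "sex": 0.0002,
}

#: marginal preterm share the default outcome intercept is calibrated to
TARGET_PRETERM_SHARE = 0.112

_PRETERM_WEEKS = np.arange(22, 37)
_PRETERM_WEEK_P = 1.35 ** (_PRETERM_WEEKS - 22.0)
_PRETERM_WEEK_P /= _PRETERM_WEEK_P.sum()
_TERM_WEEKS = np.arange(37, 43)
_TERM_WEEK_P = np.array([0.08, 0.25, 0.30, 0.22, 0.10, 0.05])


@dataclass
class SyntheticConfig:
    """Full specification of the synthetic data-generating process."""

    n_per_year: int = 20_000
    years: tuple[int, int] = (2019, 2020)
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=table1_marginals
    )
    outcome_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOME_COEFS.items()}
    )
    outcome_intercept: float | None = None  # calibrated when None
    period_effect: float = math.log(1.04)
    confounding_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONFOUNDING_COEFS.items()}
    )
    confounding_intercept: float | None = None  # calibrated when None
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    region_shares: dict[str, float] = field(default_factory=lambda: dict(REGION_SHARES))
    birthweight_preterm: tuple[float, float] = (2400.0, 600.0)
    birthweight_term: tuple[float, float] = (3300.0, 450.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_year < 1:
            raise ValueError("n_per_year must be >= 1")
        for var, dist in self.covariate_marginals.items():
            probs = np.asarray(list(dist.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"marginal probabilities for '{var}' must lie in [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal distribution for '{var}' sums to {probs.sum():.12f}, not 1"
                )
        for fld, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for '{fld}' must lie in [0, 1]")
        rprobs = np.asarray(list(self.region_shares.values()), dtype=float)
        if abs(rprobs.sum() - 1.0) > 1e-9:
            raise ValueError("region shares must sum to 1")


def default_config(**overrides) -> SyntheticConfig:
    """The generator's study conditions, with calibrated intercepts resolved."""
    cfg = replace(SyntheticConfig(), **overrides)
    cfg.validate()
    if cfg.confounding_intercept is None:
        cfg.confounding_intercept = calibrate_assignment_intercept(cfg)
    if cfg.outcome_intercept is None:
        cfg.outcome_intercept = calibrate_outcome_intercept(cfg)
    return cfg


def null_config(**overrides) -> SyntheticConfig:
    """Confounded conditions with a zero true period effect."""
    overrides.setdefault("period_effect", 0.0)
    return default_config(**overrides)


# ---------------------------------------------------------------------------
# enumeration over the finite covariate space


def _levels(cfg: SyntheticConfig) -> dict[str, list[str]]:
    return {v: list(cfg.covariate_marginals[v]) for v in COVARIATES}


def _coef_array(levels: list[str], coefs: dict[str, float]) -> np.ndarray:
    return np.array([coefs.get(lv, 0.0) for lv in levels])


def enumerate_cells(cfg: SyntheticConfig):
    """All covariate combinations with their probabilities and linear scores.

    Returns ``(prob, s_out, s_conf)``: cell probability under independent
    marginals, outcome score and assignment score (both without intercept).
    """
    levels = _levels(cfg)
    shapes = [len(levels[v]) for v in COVARIATES]
    idx = np.indices(shapes).reshape(len(COVARIATES), -1)
    prob = np.ones(idx.shape[1])
    s_out = np.zeros(idx.shape[1])
    s_conf = np.zeros(idx.shape[1])
    for i, var in enumerate(COVARIATES):
        marg = np.array([cfg.covariate_marginals[var][lv] for lv in levels[var]])
        prob *= marg[idx[i]]
        s_out += _coef_array(levels[var], cfg.outcome_coefs.get(var, {}))[idx[i]]
        s_conf += _coef_array(levels[var], cfg.confounding_coefs.get(var, {}))[idx[i]]
    return prob, s_out, s_conf


def calibrate_assignment_intercept(cfg: SyntheticConfig, target: float = 0.5) -> float:
    """Intercept making the marginal later-year share equal ``target``."""
    prob, _, s_conf = enumerate_cells(cfg)
    f = lambda a: float(prob @ expit(a + s_conf)) - target
    return brentq(f, -20.0, 20.0, xtol=1e-12)


def calibrate_outcome_intercept(
    cfg: SyntheticConfig, target: float = TARGET_PRETERM_SHARE
) -> float:
    """Intercept making the marginal preterm share equal ``target``.

    Accounts for the period mix: the share is averaged over the confounded
    assignment and the period effect.
    """
    prob, s_out, s_conf = enumerate_cells(cfg)
    a_conf = (
        cfg.confounding_intercept
        if cfg.confounding_intercept is not None
        else calibrate_assignment_intercept(cfg)
    )
    e = expit(a_conf + s_conf)

    def share(a: float) -> float:
        p0 = expit(a + s_out)
        p1 = expit(a + s_out + cfg.period_effect)
        return float(prob @ ((1.0 - e) * p0 + e * p1)) - target

    return brentq(share, -20.0, 10.0, xtol=1e-12)


def enumerate_marginal_or(cfg: SyntheticConfig) -> float:
    """Exact population marginal odds ratio of the period on preterm birth.

    Brute-force enumeration: the odds of preterm under "everyone in the later
    year" versus "everyone in the earlier year", averaged over the full
    covariate distribution.
    """
    prob, s_out, _ = enumerate_cells(cfg)
    a = _resolved(cfg).outcome_intercept
    p1 = float(prob @ expit(a + s_out + cfg.period_effect))
    p0 = float(prob @ expit(a + s_out))
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def enumerate_crude_or(cfg: SyntheticConfig) -> float:
    """Exact crude (unadjusted) odds ratio of the period on preterm birth.

    Computed from the population joint distribution of (z, y); differs from
    the marginal causal odds ratio when confounding is present.
    """
    cfg = _resolved(cfg)
    prob, s_out, s_conf = enumerate_cells(cfg)
    e = expit(cfg.confounding_intercept + s_conf)
    p1 = expit(cfg.outcome_intercept + s_out + cfg.period_effect)
    p0 = expit(cfg.outcome_intercept + s_out)
    n11 = float(prob @ (e * p1))
    n10 = float(prob @ (e * (1 - p1)))
    n01 = float(prob @ ((1 - e) * p0))
    n00 = float(prob @ ((1 - e) * (1 - p0)))
    return (n11 * n00) / (n10 * n01)


def true_marginal_or(cfg: SyntheticConfig, n_mc: int) -> float:
    """Monte-Carlo estimate of the population marginal odds ratio of z on y.

    Deterministic given ``cfg.seed``; the exact companion is
    :func:`enumerate_marginal_or`.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    cfg = _resolved(cfg)
    rng = np.random.default_rng((cfg.seed, 104_729))
    idx = _draw_covariates(cfg, rng, n_mc)
    s_out = _score(cfg, idx, cfg.outcome_coefs)
    p1 = float(np.mean(expit(cfg.outcome_intercept + s_out + cfg.period_effect)))
    p0 = float(np.mean(expit(cfg.outcome_intercept + s_out)))
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def _resolved(cfg: SyntheticConfig) -> SyntheticConfig:
    if cfg.outcome_intercept is None or cfg.confounding_intercept is None:
        return default_config(**{f.name: getattr(cfg, f.name) for f in cfg.__dataclass_fields__.values()})
    return cfg


# ---------------------------------------------------------------------------
# simulation


def _draw_covariates(cfg: SyntheticConfig, rng: np.random.Generator, n: int):
    """Level-index arrays per covariate, drawn from the marginals."""
    levels = _levels(cfg)
    idx = {}
    for var in COVARIATES:
        p = np.array([cfg.covariate_marginals[var][lv] for lv in levels[var]])
        idx[var] = rng.choice(len(p), size=n, p=p)
    return idx


def _score(cfg: SyntheticConfig, idx, coefs: dict[str, dict[str, float]]) -> np.ndarray:
    levels = _levels(cfg)
    n = len(next(iter(idx.values())))
    s = np.zeros(n)
    for var in COVARIATES:
        s += _coef_array(levels[var], coefs.get(var, {}))[idx[var]]
    return s


def _raw_fields_from_levels(cfg, idx, y, rng) -> dict[str, np.ndarray]:
    """Materialise registry-coded raw fields from category indices and outcome."""
    levels = _levels(cfg)
    lab = {v: np.asarray(levels[v], dtype=object)[idx[v]] for v in COVARIATES}
    n = len(y)

    def inv(codes: dict[int, str], labels: np.ndarray) -> np.ndarray:
        lut = {lbl: code for code, lbl in codes.items()}
        return np.array([lut[l] for l in labels], dtype=np.int64)

    maternal_age = np.where(
        lab["age_cat"] == "<19",
        rng.integers(13, 19, size=n),
        np.where(lab["age_cat"] == "19-34", rng.integers(19, 35, size=n), rng.integers(35, 46, size=n)),
    )
    schooling = np.where(
        lab["schooling_cat"] == "0-7",
        rng.integers(0, 8, size=n),
        np.where(lab["schooling_cat"] == "8-11", rng.integers(8, 12, size=n), rng.integers(12, 18, size=n)),
    )
    anc = np.select(
        [lab["anc_cat"] == "none", lab["anc_cat"] == "1-3", lab["anc_cat"] == "4-6"],
        [np.zeros(n, dtype=np.int64), rng.integers(1, 4, size=n), rng.integers(4, 7, size=n)],
        default=rng.integers(7, 16, size=n),
    )
    parity = np.where(lab["parity_cat"] == "primiparous", 0, rng.integers(1, 6, size=n))
    ga = np.where(
        y == 1,
        rng.choice(_PRETERM_WEEKS, size=n, p=_PRETERM_WEEK_P),
        rng.choice(_TERM_WEEKS, size=n, p=_TERM_WEEK_P),
    )
    mean = np.where(y == 1, cfg.birthweight_preterm[0], cfg.birthweight_term[0])
    sd = np.where(y == 1, cfg.birthweight_preterm[1], cfg.birthweight_term[1])
    bw = np.maximum(rng.normal(mean, sd), 300.0).round().astype(np.int64)
    regions = rng.choice(
        np.asarray(list(cfg.region_shares), dtype=object),
        size=n,
        p=np.array(list(cfg.region_shares.values())),
    )
    return {
        "gestational_age": ga.astype(np.int64),
        "maternal_age": maternal_age.astype(np.int64),
        "race": inv(RACE_CODES, lab["race_cat"]),
        "schooling_years": schooling.astype(np.int64),
        "marital_status": inv(MARITAL_CODES, lab["marital_cat"]),
        "parity": parity.astype(np.int64),
        "pregnancy_type": inv(PREGNANCY_CODES, lab["pregnancy_cat"]),
        "delivery_mode": inv(DELIVERY_CODES, lab["delivery_cat"]),
        "sex": inv(SEX_CODES, lab["sex_cat"]),
        "birthweight": bw,
        "anc_visits": anc.astype(np.int64),
        "region": regions,
    }


def _apply_missingness(df: pd.DataFrame, rates: dict[str, float], rng) -> pd.DataFrame:
    for fld, rate in rates.items():
        if rate <= 0 or fld not in df.columns:
            continue
        mask = rng.random(len(df)) < rate
        if mask.any():
            df.loc[mask, fld] = pd.NA
    return df


def simulate_births(cfg: SyntheticConfig) -> pd.DataFrame:
    """Simulate a two-year registry extract with confounded period assignment.

    Returns ``2 * n_per_year`` raw records.  The period indicator is drawn
    with probability ``logistic(confounding)``, the outcome with probability
    ``logistic(outcome + period_effect * z)``; gestational age, birthweight
    and the remaining raw codes are materialised consistently with the drawn
    categories, and missingness is applied last, independently per field.
    Identical (config, seed) yields bit-identical output.
    """
    cfg = _resolved(cfg)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_year
    idx = _draw_covariates(cfg, rng, n)
    s_conf = _score(cfg, idx, cfg.confounding_coefs)
    z = (rng.random(n) < expit(cfg.confounding_intercept + s_conf)).astype(np.int64)
    s_out = _score(cfg, idx, cfg.outcome_coefs)
    p_y = expit(cfg.outcome_intercept + s_out + cfg.period_effect * z)
    y = (rng.random(n) < p_y).astype(np.int64)

    fields = _raw_fields_from_levels(cfg, idx, y, rng)
    df = pd.DataFrame({"year": np.asarray(cfg.years)[z], **fields})
    for col in df.columns:
        if col != "region":
            df[col] = df[col].astype("Int64")
    df = _apply_missingness(df, cfg.missing_rates, rng)
    return df[list(RAW_FIELDS)]


def simulate_registry(
    cfg: SyntheticConfig,
    years: list[int],
    year_effects: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Simulate a multi-year registry with per-year true effects.

    Each year contributes ``n_per_year`` independent draws from the same
    covariate marginals; ``year_effects`` maps year to the true log-odds shift
    of preterm birth relative to the calibrated baseline (default 0).  Unlike
    :func:`simulate_births`, year membership here is not confounded with
    covariates — this generator serves multi-year pipeline drivers, while the
    pairwise generator carries the confounding mechanisms under test.
    """
    cfg = _resolved(cfg)
    cfg.validate()
    year_effects = year_effects or {}
    rng = np.random.default_rng((cfg.seed, 7919))
    frames = []
    for year in years:
        n = cfg.n_per_year
        idx = _draw_covariates(cfg, rng, n)
        s_out = _score(cfg, idx, cfg.outcome_coefs)
        p_y = expit(cfg.outcome_intercept + s_out + year_effects.get(year, 0.0))
        y = (rng.random(n) < p_y).astype(np.int64)
        fields = _raw_fields_from_levels(cfg, idx, y, rng)
        frame = pd.DataFrame({"year": np.full(n, year, dtype=np.int64), **fields})
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    for col in df.columns:
        if col != "region":
            df[col] = df[col].astype("Int64")
    df = _apply_missingness(df, cfg.missing_rates, rng)
    return df[list(RAW_FIELDS)]


def write_births(df: pd.DataFrame, path) -> None:
    """Write raw records in the delimited format the reader consumes."""
    df.to_csv(path, sep=";", index=False)
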