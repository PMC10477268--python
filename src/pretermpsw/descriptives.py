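"""Descriptive surfaces: prevalence shares, caesarean rates by gestational-age
band, and the caesarean-among-preterm odds ratio.

Prevalence percentages follow the national descriptive-table convention: the
denominator is all live births of the year, including "not stated" categories,
so the "unknown" rows carry their own share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import psw
from .registry_io import CATEGORY_COLUMNS

#: standard perinatal gestational-age grouping (weeks, inclusive; None = open)
DEFAULT_GA_BANDS: tuple[tuple[int, int | None], ...] = (
    (22, 27),
    (28, 31),
    (32, 36),
    (37, None),
)


def prevalence_table(
    records: pd.DataFrame,
    years: list[int] | None = None,
    variables: tuple[str, ...] | list[str] = CATEGORY_COLUMNS,
    weights: str | None = None,
) -> pd.DataFrame:
    """Counts and percentage shares per (year, variable, category).

    ``percent = 100 * count / total births that year`` with the all-births
    denominator (unknown categories included).  ``weights`` may name a column
    holding per-row counts, so published category totals can be fed as
    one-row-per-category fixtures.  ``percent`` is rounded to 2 decimals;
    ``share`` retains full precision.
    """
    if years is not None:
        records = records[records["year"].isin(years)]
    w = records[weights] if weights else pd.Series(1, index=records.index)
    totals = w.groupby(records["year"]).sum()
    rows = []
    for var in variables:
        if var not in records.columns:
            continue
        grouped = w.groupby([records["year"], records[var].astype(object)], observed=True).sum()
        for (year, cat), n in grouped.items():
            share = n / totals.loc[year]
            rows.append(
                {
                    "year": int(year),
                    "variable": var,
                    "category": cat,
                    "count": n,
                    "share": float(share),
                    "percent": round(100.0 * float(share), 2),
                }
            )
    return pd.DataFrame(rows)


def cesarean_rate_by_ga(
    records: pd.DataFrame,
    ga_bands: tuple[tuple[int, int | None], ...] = DEFAULT_GA_BANDS,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Caesarean share among known-mode deliveries per (year, GA band).

    Rows with unknown delivery mode are excluded from the denominator; rows
    with unknown gestational age have no band and are excluded entirely.
    """
    data = records[records["gestational_age"].notna()]
    if years is not None:
        data = data[data["year"].isin(years)]
    data = data[data["delivery_cat"].astype(object).isin(["vaginal", "caesarean"])]
    rows = []
    for lo, hi in ga_bands:
        label = f"{lo}-{hi}" if hi is not None else f"{lo}+"
        in_band = data["gestational_age"] >= lo
        if hi is not None:
            in_band &= data["gestational_age"] <= hi
        sub = data[in_band]
        for year, grp in sub.groupby("year"):
            n_known = len(grp)
            n_cs = int((grp["delivery_cat"].astype(object) == "caesarean").sum())
            rows.append(
                {
                    "year": int(year),
                    "ga_band": label,
                    "n_caesarean": n_cs,
                    "n_known_mode": n_known,
                    "rate": n_cs / n_known if n_known else np.nan,
                }
            )
    return pd.DataFrame(rows)


def cesarean_or_preterm(
    records: pd.DataFrame,
    year_a: int,
    year_b: int,
    adjust: tuple[str, ...] | list[str] | None = None,
    variance: str = "model",
) -> pd.DataFrame:
    """Odds ratio of caesarean delivery in ``year_b`` vs ``year_a`` among
    preterm births.

    Logistic regression of caesarean (1) vs vaginal (0) on the period
    indicator, optionally adjusted for further covariates; fitted with the
    same machinery as the PSW models.  Returns the coefficient table with the
    period term labelled ``year``.
    """
    data = records[
        (records["ga_cat"].astype(object) == "preterm")
        & records["year"].isin([year_a, year_b])
        & records["delivery_cat"].astype(object).isin(["vaginal", "caesarean"])
    ].copy()
    for year in (year_a, year_b):
        if not (data["year"] == year).any():
            raise ValueError(f"no preterm records for year {year}")
    z = (data["year"] == year_b).astype(float)
    outcome = (data["delivery_cat"].astype(object) == "caesarean").astype(float)
    if adjust:
        design = psw.build_design(data, covariates=tuple(adjust))
        X = design.X.copy()
        X.insert(0, "year", z.loc[X.index].to_numpy())
        outcome = outcome.loc[X.index]
    else:
        X = pd.DataFrame({"year": z.to_numpy()}, index=data.index)
    fit = psw.fit_logistic(X, outcome.to_numpy())
    return psw.coefficient_table(fit, variance=variance)
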