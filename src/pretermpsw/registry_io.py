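"""Reading and recoding of live-birth registry microdata.

The package consumes registry-style delimited text exports, one row per live
birth.  Raw fields use simple integer codes documented below (a configurable
column mapping and per-column missing codes adapt other dialects):

======================  =======================================================
field                   coding
======================  =======================================================
year                    calendar year of birth
gestational_age         completed weeks at delivery
maternal_age            years
race                    1 white, 2 black, 3 asian, 4 brown, 5 indigenous
schooling_years         completed years of schooling
marital_status          1 single, 2 married/cohabiting, 3 widowed, 4 divorced
parity                  number of prior deliveries
pregnancy_type          1 singleton, 2 twin, 3 triplet or higher
delivery_mode           1 vaginal, 2 caesarean
sex                     1 male, 2 female
birthweight             grams
anc_visits              number of antenatal care visits
region                  macro-region name or two-letter state code
======================  =======================================================

:func:`recode` maps raw records onto the closed category sets of the national
descriptive table (maternal age bands <19 / 19-34 / >34, schooling 0-7 / 8-11 /
12+, antenatal visits none / 1-3 / 4-6 / 7+, ...), derives the preterm outcome
``y`` (1 for 22-36 completed weeks, 0 for >=37) and the eligibility flag
(births below 22 weeks are excluded from all analyses).  Records with unknown
gestational age keep ``y`` undefined: they enter descriptive denominators but
never model fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_FIELDS: tuple[str, ...] = (
    "year",
    "gestational_age",
    "maternal_age",
    "race",
    "schooling_years",
    "marital_status",
    "parity",
    "pregnancy_type",
    "delivery_mode",
    "sex",
    "birthweight",
    "anc_visits",
    "region",
)

_NUMERIC_FIELDS = tuple(f for f in RAW_FIELDS if f != "region")

RACE_CODES = {1: "white", 2: "black", 3: "asian", 4: "brown", 5: "indigenous"}
MARITAL_CODES = {1: "single", 2: "married/cohabit", 3: "widow", 4: "divorced"}
DELIVERY_CODES = {1: "vaginal", 2: "caesarean"}
SEX_CODES = {1: "male", 2: "female"}
PREGNANCY_CODES = {1: "single", 2: "twin", 3: "triplet+"}

REGIONS = ("North", "Northeast", "Southeast", "South", "Midwest")

#: Brazilian federal units mapped onto macro-regions.
STATE_TO_REGION = {
    "AC": "North", "AM": "North", "AP": "North", "PA": "North",
    "RO": "North", "RR": "North", "TO": "North",
    "AL": "Northeast", "BA": "Northeast", "CE": "Northeast", "MA": "Northeast",
    "PB": "Northeast", "PE": "Northeast", "PI": "Northeast", "RN": "Northeast",
    "SE": "Northeast",
    "ES": "Southeast", "MG": "Southeast", "RJ": "Southeast", "SP": "Southeast",
    "PR": "South", "RS": "South", "SC": "South",
    "DF": "Midwest", "GO": "Midwest", "MS": "Midwest", "MT": "Midwest",
}

#: closed category sets of the recoded analysis table
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "ga_cat": ("term", "preterm", "unknown"),
    "age_cat": ("<19", "19-34", ">34"),
    "parity_cat": ("primiparous", "multiparous"),
    "delivery_cat": ("vaginal", "caesarean", "unknown"),
    "sex_cat": ("female", "male", "unknown"),
    "race_cat": ("white", "black", "asian", "brown", "indigenous", "unknown"),
    "schooling_cat": ("0-7", "8-11", "12+", "unknown"),
    "marital_cat": ("single", "married/cohabit", "widow", "divorced", "unknown"),
    "pregnancy_cat": ("single", "twin", "triplet+", "unknown"),
    "anc_cat": ("none", "1-3", "4-6", "7+", "unknown"),
}

CATEGORY_COLUMNS = tuple(CATEGORY_LEVELS)

RECODED_COLUMNS = (
    "year",
    "region",
    "gestational_age",
    "birthweight",
    "y",
    "eligible",
) + CATEGORY_COLUMNS


@dataclass
class ReadReport:
    """Per-column accounting of what happened while reading a raw file."""

    n_rows: int = 0
    coercion_failures: dict[str, int] = field(default_factory=dict)
    missing_replaced: dict[str, int] = field(default_factory=dict)

    @property
    def n_coercion_failures(self) -> int:
        return sum(self.coercion_failures.values())


@dataclass
class ReadResult:
    records: pd.DataFrame
    report: ReadReport


def read_births(
    path,
    schema: dict[str, str] | None = None,
    missing_codes: dict[str, set] | None = None,
    delimiter: str = ";",
) -> ReadResult:
    """Read a registry-style delimited file into a raw birth-record table.

    Parameters
    ----------
    path
        Delimited text file, UTF-8, one row per birth.
    schema
        Mapping ``field -> column name in the file``; defaults to identity.
    missing_codes
        Per-field set of raw strings to treat as "not stated" (e.g.
        ``{"gestational_age": {"99"}}``).  Declared codes become missing
        values; they never coerce silently to valid categories.
    delimiter
        Field separator (registry exports commonly use ``;``).

    Cells that are neither parseable nor declared missing are set to missing
    and counted per column in the report — rows are never silently dropped.
    """
    schema = dict(schema or {})
    missing_codes = {k: {str(v) for v in vals} for k, vals in (missing_codes or {}).items()}
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    except FileNotFoundError:
        raise FileNotFoundError(f"registry file not found: {path}")
    report = ReadReport(n_rows=len(raw))

    records = pd.DataFrame(index=raw.index)
    for fld in RAW_FIELDS:
        col = schema.get(fld, fld)
        if col not in raw.columns:
            raise ValueError(f"required column missing from {path}: '{col}' (field '{fld}')")
        s = raw[col].str.strip()
        s = s.replace("", pd.NA)
        codes = missing_codes.get(fld)
        if codes:
            declared = s.isin(codes)
            report.missing_replaced[fld] = int(declared.sum())
            s = s.mask(declared)
        if fld in _NUMERIC_FIELDS:
            num = pd.to_numeric(s, errors="coerce")
            failed = int((num.isna() & s.notna()).sum())
            if failed:
                report.coercion_failures[fld] = failed
            records[fld] = num.astype("Float64").round().astype("Int64")
        else:
            records[fld] = s
    return ReadResult(records=records, report=report)


def _categorize(values: pd.Series, levels: tuple[str, ...]) -> pd.Series:
    return pd.Series(
        pd.Categorical(values, categories=list(levels)), index=values.index
    )


def _band(
    values: pd.Series, edges: list[tuple[float, float, str]], unknown: str = "unknown"
) -> pd.Series:
    """Map a numeric series onto labelled closed bands; NA -> unknown."""
    out = pd.Series(unknown, index=values.index, dtype=object)
    v = values.astype("Float64")
    for lo, hi, label in edges:
        out[(v >= lo) & (v <= hi)] = label
    return out


def recode(
    records: pd.DataFrame, preterm_upper: int = 36, lower_bound: int = 22
) -> pd.DataFrame:
    """Recode raw birth records into the analysis categories.

    ``ga_cat`` is "preterm" for ``lower_bound <= weeks <= preterm_upper``,
    "term" for ``weeks >= preterm_upper + 1`` and "unknown" when missing;
    ``y`` mirrors the term/preterm dichotomy and is undefined for unknown
    gestational ages.  ``eligible`` is False exactly when the gestational age
    is known and below ``lower_bound``.  Recoding is total: every raw value
    lands in a closed category set or "unknown".
    """
    out = pd.DataFrame(index=records.index)
    out["year"] = records["year"].astype("Int64")
    region = records["region"].astype(object)
    out["region"] = region.map(lambda r: STATE_TO_REGION.get(r, r) if pd.notna(r) else r)
    ga = records["gestational_age"].astype("Float64")
    out["gestational_age"] = records["gestational_age"].astype("Int64")
    out["birthweight"] = records["birthweight"].astype("Float64")

    ga_cat = pd.Series("unknown", index=records.index, dtype=object)
    ga_cat[(ga >= lower_bound) & (ga <= preterm_upper)] = "preterm"
    ga_cat[ga >= preterm_upper + 1] = "term"
    # below-threshold births are ineligible; keep them out of the outcome bands
    ga_cat[ga < lower_bound] = "unknown"
    out["y"] = pd.Series(pd.NA, index=records.index, dtype="Int64")
    out.loc[ga_cat == "preterm", "y"] = 1
    out.loc[ga_cat == "term", "y"] = 0
    out["eligible"] = ~((ga.notna()) & (ga < lower_bound))

    out["ga_cat"] = _categorize(ga_cat, CATEGORY_LEVELS["ga_cat"])
    out["age_cat"] = _categorize(
        _band(records["maternal_age"], [(0, 18, "<19"), (19, 34, "19-34"), (35, np.inf, ">34")]),
        CATEGORY_LEVELS["age_cat"],
    )
    parity = pd.Series("unknown", index=records.index, dtype=object)
    p = records["parity"].astype("Float64")
    parity[p == 0] = "primiparous"
    parity[p >= 1] = "multiparous"
    # parity is a two-level split; unknown parity is rare and treated as multiparous-missing
    out["parity_cat"] = pd.Series(
        pd.Categorical(parity.replace("unknown", None), categories=["primiparous", "multiparous"]),
        index=records.index,
    )
    out["delivery_cat"] = _categorize(
        _coded(records["delivery_mode"], DELIVERY_CODES), CATEGORY_LEVELS["delivery_cat"]
    )
    out["sex_cat"] = _categorize(
        _coded(records["sex"], SEX_CODES), CATEGORY_LEVELS["sex_cat"]
    )
    out["race_cat"] = _categorize(
        _coded(records["race"], RACE_CODES), CATEGORY_LEVELS["race_cat"]
    )
    out["schooling_cat"] = _categorize(
        _band(records["schooling_years"], [(0, 7, "0-7"), (8, 11, "8-11"), (12, np.inf, "12+")]),
        CATEGORY_LEVELS["schooling_cat"],
    )
    out["marital_cat"] = _categorize(
        _coded(records["marital_status"], MARITAL_CODES), CATEGORY_LEVELS["marital_cat"]
    )
    out["pregnancy_cat"] = _categorize(
        _coded(records["pregnancy_type"], PREGNANCY_CODES), CATEGORY_LEVELS["pregnancy_cat"]
    )
    out["anc_cat"] = _categorize(
        _band(
            records["anc_visits"],
            [(0, 0, "none"), (1, 3, "1-3"), (4, 6, "4-6"), (7, np.inf, "7+")],
        ),
        CATEGORY_LEVELS["anc_cat"],
    )
    return out[list(RECODED_COLUMNS)]


def _coded(values: pd.Series, codes: dict[int, str]) -> pd.Series:
    v = values.astype("Float64")
    out = pd.Series("unknown", index=values.index, dtype=object)
    for code, label in codes.items():
        out[v == code] = label
    return out


def filter_eligible(recoded: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the records satisfying the gestational-age inclusion rule.

    Multiple pregnancies are retained; only births below the lower gestational
    bound (default 22 weeks) are excluded.
    """
    return recoded[recoded["eligible"]].copy()


def write_recoded(recoded: pd.DataFrame, path) -> None:
    """Write a recoded analysis table as semicolon-delimited CSV."""
    recoded.to_csv(path, sep=";", index=False)


def read_recoded(path) -> pd.DataFrame:
    """Read a recoded analysis table back, restoring categorical dtypes."""
    df = pd.read_csv(path, sep=";", dtype={"region": str})
    for col, levels in CATEGORY_LEVELS.items():
        if col == "parity_cat":
            df[col] = pd.Categorical(df[col], categories=["primiparous", "multiparous"])
        else:
            df[col] = pd.Categorical(df[col], categories=list(levels))
    for col in ("year", "gestational_age", "y"):
        df[col] = df[col].astype("Float64").astype("Int64")
    df["birthweight"] = df["birthweight"].astype("Float64")
    df["eligible"] = df["eligible"].astype(bool)
    return df[list(RECODED_COLUMNS)]


def recode_report(recoded: pd.DataFrame) -> pd.DataFrame:
    """Counts per category per year for every recoded variable (audit table)."""
    rows = []
    for col in CATEGORY_COLUMNS:
        counts = (
            recoded.groupby(["year", col], observed=False).size().rename("n").reset_index()
        )
        counts["variable"] = col
        counts = counts.rename(columns={col: "category"})
        rows.append(counts[["year", "variable", "category", "n"]])
    return pd.concat(rows, ignore_index=True)
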