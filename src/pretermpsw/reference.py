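"""Reference constants: published national registry descriptives, 2019-2021.

``TABLE1_COUNTS`` holds the printed per-category birth counts of the Brazilian
live-birth registry (SINASC) descriptive table for 2019, 2020 and 2021, keyed by
the recoded category columns this package produces.  They serve two purposes:

* the 2019 column provides the default covariate marginals for the synthetic
  registry generator (:mod:`pretermpsw.synthetic`);
* fed as category-weighted fixtures to :func:`pretermpsw.descriptives.prevalence_table`
  they reproduce the published percentage shares, which the test suite checks.

``TABLE1_PERCENTS`` stores the percentages exactly as printed.  A handful of
printed cells are internally inconsistent with their own counts (the source
mixes rounding and truncation, and its 2020 schooling column is garbled);
``TABLE1_ERRATA`` lists the (year, variable) cells excluded from exact checks.
"""

from __future__ import annotations

import pandas as pd

#: total live births per year (all categories, including "not stated")
TABLE1_TOTALS: dict[int, int] = {2019: 2_849_146, 2020: 2_730_145, 2021: 2_672_046}

#: printed counts per (variable, category, year)
TABLE1_COUNTS: dict[str, dict[str, dict[int, int]]] = {
    "ga_cat": {
        "term": {2019: 2_497_002, 2020: 2_386_104, 2021: 2_332_351},
        "preterm": {2019: 315_831, 2020: 308_702, 2021: 302_677},
        "unknown": {2019: 36_313, 2020: 35_339, 2021: 37_018},
    },
    "age_cat": {
        "<19": {2019: 295_832, 2020: 269_839, 2021: 257_026},
        "19-34": {2019: 1_989_893, 2020: 1_908_361, 2021: 1_868_652},
        ">34": {2019: 563_421, 2020: 551_945, 2021: 546_368},
    },
    "parity_cat": {
        "primiparous": {2019: 1_069_586, 2020: 1_011_438, 2021: 983_071},
        "multiparous": {2019: 1_779_560, 2020: 1_718_707, 2021: 1_688_975},
    },
    "delivery_cat": {
        "vaginal": {2019: 1_243_104, 2020: 1_165_641, 2021: 1_145_970},
        "caesarean": {2019: 1_604_189, 2020: 1_562_282, 2021: 1_524_013},
        "unknown": {2019: 1_853, 2020: 2_222, 2021: 2_063},
    },
    "sex_cat": {
        "male": {2019: 1_457_226, 2020: 1_398_043, 2021: 1_367_051},
        "female": {2019: 1_391_486, 2020: 1_331_658, 2021: 1_304_590},
        "unknown": {2019: 434, 2020: 444, 2021: 405},
    },
    "race_cat": {
        "white": {2019: 964_557, 2020: 908_547, 2021: 867_657},
        "black": {2019: 176_224, 2020: 179_416, 2021: 181_875},
        "asian": {2019: 12_738, 2020: 12_309, 2021: 12_106},
        "brown": {2019: 1_594_267, 2020: 1_533_251, 2021: 1_516_269},
        "indigenous": {2019: 26_373, 2020: 25_741, 2021: 28_216},
        "unknown": {2019: 74_987, 2020: 70_881, 2021: 65_923},
    },
    "schooling_cat": {
        "0-7": {2019: 462_063, 2020: 431_144, 2021: 379_799},
        "8-11": {2019: 1_748_186, 2020: 1_698_877, 2021: 1_673_570},
        "12+": {2019: 606_145, 2020: 589_807, 2021: 583_779},
        "unknown": {2019: 32_752, 2020: 29_178, 2021: 34_898},
    },
    "marital_cat": {
        "single": {2019: 1_285_998, 2020: 1_283_754, 2021: 1_292_963},
        "married/cohabit": {2019: 1_492_765, 2020: 1_374_363, 2021: 1_302_820},
        "widow": {2019: 4_693, 2020: 4_603, 2021: 4_978},
        "divorced": {2019: 38_748, 2020: 39_619, 2021: 39_576},
        "unknown": {2019: 26_942, 2020: 27_806, 2021: 31_709},
    },
    "pregnancy_cat": {
        "single": {2019: 2_785_200, 2020: 2_668_636, 2021: 2_611_194},
        "twin": {2019: 60_610, 2020: 57_846, 2021: 57_061},
        "triplet+": {2019: 1_467, 2020: 1_262, 2021: 1_319},
        "unknown": {2019: 1_869, 2020: 2_401, 2021: 2_472},
    },
    "anc_cat": {
        "none": {2019: 43_406, 2020: 47_276, 2021: 49_085},
        "1-3": {2019: 152_483, 2020: 164_943, 2021: 142_687},
        "4-6": {2019: 577_170, 2020: 565_211, 2021: 511_652},
        "7+": {2019: 2_063_669, 2020: 1_938_920, 2021: 1_954_282},
        "unknown": {2019: 12_418, 2020: 13_795, 2021: 14_430},
    },
}

#: percentage shares as printed (None where the printed cell is missing)
TABLE1_PERCENTS: dict[str, dict[str, dict[int, float | None]]] = {
    "ga_cat": {
        "term": {2019: 87.64, 2020: 87.40, 2021: 87.28},
        "preterm": {2019: 11.09, 2020: 11.31, 2021: 11.32},
        "unknown": {2019: 1.27, 2020: 1.30, 2021: 1.38},
    },
    "age_cat": {
        "<19": {2019: 10.38, 2020: 9.88, 2021: 9.62},
        "19-34": {2019: 69.84, 2020: 69.90, 2021: 69.93},
        ">34": {2019: 19.78, 2020: 20.22, 2021: 20.45},
    },
    "parity_cat": {
        "primiparous": {2019: 37.54, 2020: 37.04, 2021: 36.79},
        "multiparous": {2019: 62.46, 2020: 62.95, 2021: 63.20},
    },
    "delivery_cat": {
        "vaginal": {2019: 43.63, 2020: 42.69, 2021: 42.89},
        "caesarean": {2019: 56.30, 2020: 57.22, 2021: 57.04},
        "unknown": {2019: 0.07, 2020: 0.08, 2021: 0.08},
    },
    "sex_cat": {
        "male": {2019: 51.15, 2020: 51.20, 2021: 51.16},
        "female": {2019: 48.84, 2020: 48.78, 2021: 48.82},
        "unknown": {2019: 0.02, 2020: 0.02, 2021: 0.02},
    },
    "race_cat": {
        "white": {2019: 33.85, 2020: 32.26, 2021: 32.47},
        "black": {2019: 6.19, 2020: 6.34, 2021: 6.81},
        "asian": {2019: 0.45, 2020: 0.44, 2021: 0.45},
        "brown": {2019: 55.96, 2020: 57.06, 2021: 56.75},
        "indigenous": {2019: 0.93, 2020: 0.91, 2021: 1.06},
        "unknown": {2019: 2.63, 2020: None, 2021: 2.47},
    },
    "schooling_cat": {
        "0-7": {2019: 16.22, 2020: 15.36, 2021: 14.21},
        "8-11": {2019: 61.36, 2020: 62.23, 2021: 62.62},
        "12+": {2019: 21.27, 2020: 21.12, 2021: 21.48},
        "unknown": {2019: 1.15, 2020: 1.31, 2021: 1.30},
    },
    "marital_cat": {
        "single": {2019: 45.14, 2020: 47.02, 2021: 48.39},
        "married/cohabit": {2019: 52.39, 2020: 50.34, 2021: 48.76},
        "widow": {2019: 0.16, 2020: 0.17, 2021: 0.19},
        "divorced": {2019: 1.36, 2020: 1.45, 2021: 1.48},
        "unknown": {2019: 0.95, 2020: 1.02, 2021: 1.19},
    },
    "pregnancy_cat": {
        "single": {2019: 97.76, 2020: 97.74, 2021: 97.72},
        "twin": {2019: 2.13, 2020: 2.11, 2021: 2.14},
        "triplet+": {2019: 0.05, 2020: 0.05, 2021: 0.05},
        "unknown": {2019: 0.07, 2020: 0.08, 2021: 0.09},
    },
    "anc_cat": {
        "none": {2019: 1.52, 2020: 1.73, 2021: 1.84},
        "1-3": {2019: 5.35, 2020: 6.04, 2021: 5.34},
        "4-6": {2019: 20.26, 2020: 20.70, 2021: 19.15},
        "7+": {2019: 72.43, 2020: 71.01, 2021: 73.14},
        "unknown": {2019: 0.44, 2020: 0.50, 2021: 0.54},
    },
}

#: (year, variable, category) cells whose printed counts and percentages are
#: mutually inconsistent in the published table (beyond final-digit rounding)
#: and are excluded from exact reproduction checks: the 2020 schooling column
#: is garbled, the 2020 race percentages use a different denominator vintage
#: than their counts, and the 2021 schooling "12+" share is misprinted.
TABLE1_ERRATA: set[tuple[int, str, str]] = {
    (2020, "schooling_cat", "0-7"),
    (2020, "schooling_cat", "8-11"),
    (2020, "schooling_cat", "12+"),
    (2020, "schooling_cat", "unknown"),
    (2020, "race_cat", "white"),
    (2020, "race_cat", "black"),
    (2020, "race_cat", "brown"),
    (2020, "race_cat", "indigenous"),
    (2021, "schooling_cat", "12+"),
}

#: approximate share of national live births by macro-region (generator default)
REGION_SHARES: dict[str, float] = {
    "North": 0.11,
    "Northeast": 0.28,
    "Southeast": 0.38,
    "South": 0.13,
    "Midwest": 0.10,
}


def table1_fixture(variable: str, years: list[int] | None = None) -> pd.DataFrame:
    """Category-weighted fixture for one descriptive variable.

    Returns one row per (year, category) with the printed count in column
    ``n`` — the form :func:`pretermpsw.descriptives.prevalence_table` accepts
    via its ``weights`` argument.
    """
    years = years or sorted(TABLE1_TOTALS)
    rows = []
    for cat, by_year in TABLE1_COUNTS[variable].items():
        for year in years:
            rows.append({"year": year, variable: cat, "n": by_year[year]})
    return pd.DataFrame(rows)


def table1_marginals(year: int = 2019, include_unknown: bool = False) -> dict[str, dict[str, float]]:
    """Covariate marginal distributions derived from the printed counts.

    With ``include_unknown=False`` (the generator's convention) the "unknown"
    mass is removed and the remaining categories renormalised, since the
    generator applies missingness as a separate, final step.
    """
    out: dict[str, dict[str, float]] = {}
    for var, cats in TABLE1_COUNTS.items():
        if var == "ga_cat":  # outcome, not a covariate
            continue
        counts = {c: by_year[year] for c, by_year in cats.items()}
        if not include_unknown:
            counts.pop("unknown", None)
        total = sum(counts.values())
        out[var] = {c: n / total for c, n in counts.items()}
    return out
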