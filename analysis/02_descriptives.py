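#!/usr/bin/env python
"""Descriptive tables: category shares per year, caesarean rate by
gestational-age band, and the caesarean-among-preterm odds ratio.

Reads the synthetic registry written by 01_simulate_registry.py and writes
under results/:

* ``prevalence_by_year.csv`` — the descriptive-table analogue (share of each
  category per year, all-births denominator);
* ``cesarean_rate_by_ga.csv`` — caesarean share per gestational-age band;
* ``cesarean_or_preterm.csv`` — caesarean odds ratios among preterm births
  for each pairwise year comparison.

Also writes ``prevalence_published.csv``: the shares recomputed from the
packaged published registry counts (2019-2021), the desk-scale check that the
descriptive machinery reproduces the printed national percentages.
"""

from pathlib import Path

import pandas as pd

from pretermpsw import descriptives as desc, reference as ref, registry_io as rio

SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rec = rio.recode(rio.read_births(SCRATCH / "registry_5y.csv").records)

    prev = desc.prevalence_table(rec)
    prev.to_csv(RESULTS / "prevalence_by_year.csv", index=False)
    preterm = prev[(prev["variable"] == "ga_cat") & (prev["category"] == "preterm")]
    print("synthetic preterm share by year (%):")
    print(preterm.set_index("year")["percent"].to_string())

    rates = desc.cesarean_rate_by_ga(rec)
    rates.to_csv(RESULTS / "cesarean_rate_by_ga.csv", index=False)

    rows = []
    for year_a, year_b in ((2017, 2018), (2018, 2019), (2019, 2020), (2019, 2021)):
        t = desc.cesarean_or_preterm(rec, year_a, year_b).set_index("term")
        rows.append(
            {
                "pair": f"{year_a}-{year_b}",
                "or": t.loc["year", "or_"],
                "ci_low": t.loc["year", "ci_low"],
                "ci_high": t.loc["year", "ci_high"],
                "p": t.loc["year", "p"],
            }
        )
    pd.DataFrame(rows).to_csv(RESULTS / "cesarean_or_preterm.csv", index=False)

    published = pd.concat(
        desc.prevalence_table(ref.table1_fixture(var), variables=[var], weights="n")
        for var in sorted(ref.TABLE1_COUNTS)
    )
    published.to_csv(RESULTS / "prevalence_published.csv", index=False)
    ga = published[(published["variable"] == "ga_cat") & (published["category"] == "preterm")]
    print("\npublished-count preterm share by year (%):")
    print(ga.set_index("year")["percent"].to_string())


if __name__ == "__main__":
    main()
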