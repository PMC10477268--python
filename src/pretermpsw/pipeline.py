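"""Orchestration of the pairwise-year PSW design.

The study design compares consecutive (and pandemic-baseline) year pairs by
stacking two years of recoded records, defining the period indicator
``z`` (0 = earlier year, 1 = later year), and running the PSW chain —
propensity estimation, common-support trimming, inverse-probability weights,
weighted outcome regression — nationally and within macro-regions.  The
default pairs are 2017-2018, 2018-2019, 2019-2020 and 2019-2021: both
pandemic years are compared against the 2019 baseline.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import psw
from .registry_io import filter_eligible

log = logging.getLogger(__name__)

DEFAULT_PAIRS: tuple[tuple[int, int], ...] = (
    (2017, 2018),
    (2018, 2019),
    (2019, 2020),
    (2019, 2021),
)


@dataclass
class StackedDataset:
    """Two years of modelling-ready records with the period indicator."""

    data: pd.DataFrame  # recoded columns + z; y defined on every row
    year_a: int
    year_b: int
    region: str | None = None

    @property
    def pair_label(self) -> str:
        return f"{self.year_a}-{self.year_b}"


@dataclass
class PSWConfig:
    """Knobs of one PSW cell fit."""

    ps_covariates: tuple[str, ...] = psw.DEFAULT_PS_COVARIATES
    outcome_covariates: tuple[str, ...] = psw.DEFAULT_OUTCOME_COVARIATES
    trim_fraction: float = 0.10
    eps: float = 1e-6
    variance: str = "model"
    reference_levels: dict[str, str] | None = None
    refit_ps_per_region: bool = True


@dataclass
class CellResult:
    pair_label: str
    region: str
    n_before: int
    n_after: int
    fit: psw.PSWFit | None = None
    scores: psw.PropensityScores | None = None
    error: str | None = None


@dataclass
class PairwiseResult:
    summary: pd.DataFrame
    cells: dict[tuple[str, str], CellResult] = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return bool(self.summary["error"].notna().any())


def build_stacked(
    recoded: pd.DataFrame,
    year_a: int,
    year_b: int,
    region: str | None = None,
) -> StackedDataset:
    """Stack two years of recoded records and attach the period indicator.

    Applies the eligibility rule, drops records with undefined outcome
    (unknown gestational age), optionally filters to one macro-region, and
    sets ``z = 0`` for ``year_a`` rows and ``z = 1`` for ``year_b`` rows.
    """
    if year_a >= year_b:
        raise ValueError(f"year_a must precede year_b: {year_a} >= {year_b}")
    data = filter_eligible(recoded)
    data = data[data["y"].notna()]
    if region is not None and region != "Brazil":
        data = data[data["region"] == region]
    data = data[data["year"].isin([year_a, year_b])].copy()
    for year in (year_a, year_b):
        if not (data["year"] == year).any():
            raise ValueError(f"no records for year {year}" + (f" in region {region}" if region else ""))
    data["z"] = (data["year"] == year_b).astype(int)
    return StackedDataset(data=data, year_a=year_a, year_b=year_b, region=region)


def run_cell(stacked: StackedDataset, config: PSWConfig | None = None) -> CellResult:
    """Run the full PSW chain on one stacked dataset.

    This is literally the sequence estimate_propensity -> trim_tails ->
    compute_weights -> fit_outcome_model; running the stages manually on the
    same input reproduces the result bit for bit.
    """
    config = config or PSWConfig()
    region = stacked.region or "Brazil"
    scores = psw.estimate_propensity(
        stacked,
        ps_covariates=config.ps_covariates,
        eps=config.eps,
        reference_levels=config.reference_levels,
    )
    retained = psw.trim_tails(scores.e, fraction=config.trim_fraction)
    weights = psw.compute_weights(scores.e[retained], stacked.data.loc[scores.e[retained].index, "z"])
    fit = psw.fit_outcome_model(
        stacked,
        retained,
        weights,
        outcome_covariates=config.outcome_covariates,
        variance=config.variance,
        reference_levels=config.reference_levels,
    )
    return CellResult(
        pair_label=stacked.pair_label,
        region=region,
        n_before=len(stacked.data),
        n_after=int(retained.sum()),
        fit=fit,
        scores=scores,
    )


def run_pairwise_psw(
    recoded: pd.DataFrame,
    pairs: tuple[tuple[int, int], ...] = DEFAULT_PAIRS,
    regions: tuple[str, ...] = ("Brazil",),
    config: PSWConfig | None = None,
) -> PairwiseResult:
    """PSW fits for every (year pair, region) cell plus a year-OR summary.

    Per-cell failures are recorded in the summary (``error`` column) and do
    not interrupt the remaining cells.  The summary's year-OR is exactly the
    ``year`` term of the cell's coefficient table.
    """
    config = config or PSWConfig()
    rows = []
    cells: dict[tuple[str, str], CellResult] = {}
    for year_a, year_b in pairs:
        for region in regions:
            label = f"{year_a}-{year_b}"
            t0 = time.perf_counter()
            try:
                stacked = build_stacked(recoded, year_a, year_b, region=region)
                cell = run_cell(stacked, config)
            except Exception as exc:  # recorded, run continues
                cell = CellResult(pair_label=label, region=region, n_before=0, n_after=0, error=str(exc))
            cells[(label, region)] = cell
            elapsed = time.perf_counter() - t0
            if cell.fit is not None:
                ci_low, ci_high = cell.fit.year_ci()
                year_row = cell.fit.table[cell.fit.table["term"] == "year"].iloc[0]
                rows.append(
                    {
                        "pair": label,
                        "region": region,
                        "n_before": cell.n_before,
                        "n_after": cell.n_after,
                        "n_model": cell.fit.n_model,
                        "year_or": cell.fit.year_or,
                        "ci_low": ci_low,
                        "ci_high": ci_high,
                        "p": float(year_row["p"]),
                        "converged": cell.fit.fit.converged,
                        "separation": cell.fit.fit.separation,
                        "error": None,
                    }
                )
            else:
                rows.append(
                    {
                        "pair": label,
                        "region": region,
                        "n_before": cell.n_before,
                        "n_after": cell.n_after,
                        "n_model": 0,
                        "year_or": float("nan"),
                        "ci_low": float("nan"),
                        "ci_high": float("nan"),
                        "p": float("nan"),
                        "converged": False,
                        "separation": False,
                        "error": cell.error,
                    }
                )
            log.info(
                "cell %s/%s: n=%d->%d in %.2fs%s",
                label,
                region,
                rows[-1]["n_before"],
                rows[-1]["n_after"],
                elapsed,
                f" FAILED: {cell.error}" if cell.error else "",
            )
    summary = pd.DataFrame(rows)
    return PairwiseResult(summary=summary, cells=cells)


def write_results(result: PairwiseResult, outdir) -> None:
    """Consolidated summary CSV plus one coefficient table per fitted cell."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(outdir / "summary.csv", index=False)
    for (pair, region), cell in result.cells.items():
        if cell.fit is None:
            continue
        name = f"coefficients_{pair}_{region}".replace("/", "-") + ".csv"
        cell.fit.table.to_csv(outdir / name, index=False)
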