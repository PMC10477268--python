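"""Propensity-score weighting core: design matrices, IRLS logistic regression,
common-support trimming, inverse-probability weights, the weighted outcome
model, and balance/overlap diagnostics.

The estimation pipeline mirrors the standard quasi-experimental recipe:

1. fit a logistic model for the period indicator ``z`` given covariates and
   extract the propensity score ``e(x) = P(z = 1 | x)``;
2. prune records in the tails of the pooled score distribution (default 10%
   per tail) to restrict the analysis to the region of common support;
3. weight later-year records by ``1/e(x)`` and earlier-year records by
   ``1/(1 - e(x))`` (raw inverse-probability-of-treatment weights, no
   normalisation);
4. refit a weighted logistic regression of the preterm outcome on ``z`` and
   the covariates, reporting odds ratios with 95% confidence intervals.

Logistic fits use iteratively reweighted least squares with the weights
entering the likelihood as relative frequency weights.  The default covariance
is the inverse observed information (model-based Wald); a robust sandwich
estimator is available because a pseudo-likelihood with raw IPW weights
understates sampling variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .registry_io import CATEGORY_LEVELS

#: reference category per covariate (the published regression's REF rows)
DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "age_cat": "19-34",
    "parity_cat": "primiparous",
    "delivery_cat": "vaginal",
    "sex_cat": "female",
    "race_cat": "white",
    "schooling_cat": "12+",
    "marital_cat": "married/cohabit",
    "pregnancy_cat": "single",
    "anc_cat": "none",
}

#: propensity-model covariates (maternal and obstetric characteristics)
DEFAULT_PS_COVARIATES: tuple[str, ...] = (
    "age_cat",
    "race_cat",
    "schooling_cat",
    "parity_cat",
    "delivery_cat",
    "marital_cat",
    "anc_cat",
    "birthweight",
)

#: outcome-model covariates (the published regression's covariate set)
DEFAULT_OUTCOME_COVARIATES: tuple[str, ...] = DEFAULT_PS_COVARIATES + (
    "sex_cat",
    "pregnancy_cat",
)

#: categorical covariates whose "unknown" level is kept as an explicit
#: indicator (elsewhere unknowns are dropped, complete-case)
KEEP_UNKNOWN_LEVEL: tuple[str, ...] = ("sex_cat",)

CONTINUOUS_COVARIATES: tuple[str, ...] = ("birthweight",)


@dataclass
class DesignMatrix:
    """One-hot design matrix with reference levels and drop accounting."""

    X: pd.DataFrame
    reference_levels: dict[str, str]
    covariates: tuple[str, ...]
    n_input: int
    n_dropped_rows: int
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n_iter: int
    separation: bool
    loglik: float
    n_obs: int
    sum_weights: float
    cov_robust: pd.DataFrame | None = None

    def se(self, variance: str = "model") -> pd.Series:
        cov = self._cov_for(variance)
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)

    def _cov_for(self, variance: str) -> pd.DataFrame:
        if variance == "model":
            return self.cov
        if variance == "robust":
            if self.cov_robust is None:
                raise ValueError("robust covariance was not computed for this fit")
            return self.cov_robust
        raise ValueError(f"unknown variance method: {variance!r}")


@dataclass
class PropensityScores:
    e: pd.Series  # clipped to (eps, 1 - eps), indexed by model rows
    fit: LogisticFit
    design: DesignMatrix


@dataclass
class PSWFit:
    """Weighted outcome regression results (the published-table analogue)."""

    table: pd.DataFrame  # term, coef, se, or_, ci_low, ci_high, p
    fit: LogisticFit
    retained_mask: pd.Series
    weights: pd.Series
    n_model: int
    variance: str

    @property
    def year_or(self) -> float:
        return float(self.table.loc[self.table["term"] == "year", "or_"].iloc[0])

    def year_ci(self) -> tuple[float, float]:
        row = self.table.loc[self.table["term"] == "year"].iloc[0]
        return float(row["ci_low"]), float(row["ci_high"])


def build_design(
    records: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = DEFAULT_PS_COVARIATES,
    reference_levels: dict[str, str] | None = None,
    keep_unknown: tuple[str, ...] = KEEP_UNKNOWN_LEVEL,
) -> DesignMatrix:
    """One-hot encode categorical covariates against their reference levels.

    Rows with missing values in modelled covariates are excluded
    (complete-case), except that the "unknown" level of covariates listed in
    ``keep_unknown`` is retained as an explicit indicator column.  Columns
    constant across the remaining rows are dropped with a warning.
    """
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    refs.update(reference_levels or {})
    for cov in covariates:
        if cov not in records.columns:
            raise ValueError(f"unknown covariate: '{cov}'")
        if cov in CATEGORY_LEVELS and refs.get(cov) not in CATEGORY_LEVELS[cov]:
            raise ValueError(f"invalid reference level for '{cov}': {refs.get(cov)!r}")

    mask = pd.Series(True, index=records.index)
    for cov in covariates:
        col = records[cov]
        if cov in CATEGORY_LEVELS:
            mask &= col.notna()
            if cov not in keep_unknown:
                mask &= col.astype(object) != "unknown"
        else:
            mask &= col.notna()

    sub = records.loc[mask]
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov in CATEGORY_LEVELS:
            values = sub[cov].astype(object)
            for level in CATEGORY_LEVELS[cov]:
                if level == refs[cov]:
                    continue
                if level == "unknown" and cov not in keep_unknown:
                    continue
                cols[f"{cov}[{level}]"] = (values == level).to_numpy(dtype=float)
        else:
            cols[cov] = sub[cov].to_numpy(dtype=float)

    X = pd.DataFrame(cols, index=sub.index)
    dropped_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped_cols:
        warnings.warn(
            f"dropping constant design columns: {dropped_cols}", UserWarning, stacklevel=2
        )
        X = X.drop(columns=dropped_cols)
    return DesignMatrix(
        X=X,
        reference_levels={c: refs[c] for c in covariates if c in CATEGORY_LEVELS},
        covariates=tuple(covariates),
        n_input=len(records),
        n_dropped_rows=int((~mask).sum()),
        dropped_columns=dropped_cols,
    )


# ---------------------------------------------------------------------------
# logistic regression by IRLS


def _weighted_loglik(y, p, w) -> float:
    # clip guards log(0) for fitted probabilities at machine extremes
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    outcome,
    weights=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS with frequency weights.

    Convergence is declared when the relative change in the weighted
    log-likelihood falls below ``tol`` or the largest score component is
    below ``tol``.  The covariance is the inverse observed information at the
    optimum; a sandwich covariance (bread * per-unit weighted score outer
    products * bread) is computed alongside for robust inference under raw
    IPW weights.  Non-convergence and apparent separation (diverging
    coefficients) are flagged, never silently returned.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        index = X.index
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
        index = None
    y = np.asarray(outcome, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary (0/1)")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if len(w) != len(y):
            raise ValueError("weights and outcome lengths differ")
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
    if add_intercept:
        Xv = np.column_stack([np.ones(len(y)), Xv])
        names = ["intercept"] + names
    if Xv.shape[0] != len(y):
        raise ValueError("design and outcome lengths differ")

    beta = np.zeros(Xv.shape[1])
    ybar = float(np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6))
    if add_intercept:
        beta[0] = np.log(ybar / (1 - ybar))

    eta = Xv @ beta
    p = expit(eta)
    ll = _weighted_loglik(y, p, w)
    converged = False
    n_iter = 0
    small_changes = 0
    for n_iter in range(1, max_iter + 1):
        score = Xv.T @ (w * (y - p))
        # the score exit is kept two orders stricter than the likelihood
        # tolerance so early exits never cost odds-ratio accuracy
        if np.max(np.abs(score)) < 0.01 * tol:
            converged = True
            break
        # probability clipping keeps the information matrix non-singular
        # when rare cells are perfectly predicted
        pc = np.clip(p, 1e-10, 1 - 1e-10)
        W = w * pc * (1 - pc)
        H = Xv.T @ (Xv * W[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, score, rcond=None)
        # cap the Newton step so separated levels diverge gradually, and
        # step-halve to keep the likelihood monotone
        biggest = np.max(np.abs(step))
        if biggest > 8.0:
            step = step * (8.0 / biggest)
        for _ in range(30):
            beta_new = beta + step
            p_new = expit(Xv @ beta_new)
            ll_new = _weighted_loglik(y, p_new, w)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        beta, p, ll = beta_new, p_new, ll_new
        if rel < tol:
            # extra Newton steps after the likelihood stalls: quadratic
            # convergence then pins the optimum to near machine precision
            small_changes += 1
            if small_changes >= 3:
                converged = True
                break
        else:
            small_changes = 0

    separation = bool(np.max(np.abs(beta)) > 15.0)
    pc = np.clip(p, 1e-10, 1 - 1e-10)
    W = w * pc * (1 - pc)
    H = Xv.T @ (Xv * W[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    resid = w * (y - p)
    meat = Xv.T @ (Xv * (resid**2)[:, None])
    cov_rob = cov @ meat @ cov

    params = pd.Series(beta, index=names)
    return LogisticFit(
        params=params,
        cov=pd.DataFrame(cov, index=names, columns=names),
        converged=converged,
        n_iter=n_iter,
        separation=separation,
        loglik=ll,
        n_obs=len(y),
        sum_weights=float(w.sum()),
        cov_robust=pd.DataFrame(cov_rob, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# propensity scores, trimming, weights


def estimate_propensity(
    stacked,
    ps_covariates: tuple[str, ...] | list[str] = DEFAULT_PS_COVARIATES,
    eps: float = 1e-6,
    reference_levels: dict[str, str] | None = None,
) -> PropensityScores:
    """Fit P(z = 1 | x) on a stacked two-year dataset.

    Scores are clipped to ``[eps, 1 - eps]`` so downstream inverse weights
    stay finite.  ``stacked`` may be a :class:`~pretermpsw.pipeline.StackedDataset`
    or a DataFrame carrying a ``z`` column.
    """
    data = getattr(stacked, "data", stacked)
    if "z" not in data.columns:
        raise ValueError("stacked data must define the period indicator 'z'")
    design = build_design(data, ps_covariates, reference_levels=reference_levels)
    z = data.loc[design.X.index, "z"].to_numpy(dtype=float)
    fit = fit_logistic(design.X, z)
    eta = fit.params["intercept"] + design.X.to_numpy(dtype=float) @ fit.params.iloc[1:].to_numpy()
    e = pd.Series(np.clip(expit(eta), eps, 1 - eps), index=design.X.index, name="e")
    return PropensityScores(e=e, fit=fit, design=design)


def trim_tails(e: pd.Series, fraction: float = 0.10) -> pd.Series:
    """Common-support trimming mask on the pooled score distribution.

    Removes records strictly outside the empirical ``[Q(f), Q(1 - f)]``
    interval of the pooled (both-periods) score vector, using the
    median-unbiased quantile estimate.  Ties at the cut points are retained;
    with distinct scores and ``f = 0.10`` this keeps 80% of the records.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError(f"per-tail fraction must lie in [0, 0.5): {fraction}")
    values = np.asarray(e, dtype=float)
    if fraction == 0.0:
        return pd.Series(True, index=e.index)
    lo = np.quantile(values, fraction, method="median_unbiased")
    hi = np.quantile(values, 1.0 - fraction, method="median_unbiased")
    return pd.Series((values >= lo) & (values <= hi), index=e.index)


def compute_weights(e: pd.Series, z) -> pd.Series:
    """Raw inverse-probability-of-treatment weights.

    Later-year (treated) records get ``1/e(x)``; earlier-year (control)
    records get ``1/(1 - e(x))``.  No normalisation is applied.
    """
    ev = np.asarray(e, dtype=float)
    assert ((ev > 0) & (ev < 1)).all(), "propensity scores must lie strictly in (0, 1)"
    zv = np.asarray(z, dtype=float)
    w = np.where(zv == 1, 1.0 / ev, 1.0 / (1.0 - ev))
    return pd.Series(w, index=e.index, name="w")


def coefficient_table(fit: LogisticFit, variance: str = "model", level: float = 0.95) -> pd.DataFrame:
    """Odds-ratio table (term, coef, se, OR, CI bounds, p) from a fit."""
    se = fit.se(variance)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    coef = fit.params
    with np.errstate(over="ignore"):
        table = pd.DataFrame(
            {
                "term": coef.index,
                "coef": coef.to_numpy(),
                "se": se.to_numpy(),
                "or_": np.exp(coef.to_numpy()),
                "ci_low": np.exp(coef.to_numpy() - zcrit * se.to_numpy()),
                "ci_high": np.exp(coef.to_numpy() + zcrit * se.to_numpy()),
                "p": 2 * stats.norm.sf(np.abs(coef.to_numpy() / se.to_numpy())),
            }
        ).reset_index(drop=True)
    return table


def fit_outcome_model(
    stacked,
    retained_mask: pd.Series,
    weights: pd.Series,
    outcome_covariates: tuple[str, ...] | list[str] = DEFAULT_OUTCOME_COVARIATES,
    variance: str = "model",
    reference_levels: dict[str, str] | None = None,
) -> PSWFit:
    """Weighted logistic regression of the preterm outcome on z + covariates.

    Restricted to trimming survivors with defined weights; rows additionally
    dropped by the outcome design's complete-case policy are excluded from
    the fit (and counted in the design).  The period term is reported as
    ``year``.
    """
    data = getattr(stacked, "data", stacked)
    design = build_design(data, outcome_covariates, reference_levels=reference_levels)
    retained = retained_mask[retained_mask].index
    idx = design.X.index.intersection(retained).intersection(weights.index)
    X = design.X.loc[idx].copy()
    X.insert(0, "year", data.loc[idx, "z"].to_numpy(dtype=float))
    y = data.loc[idx, "y"].to_numpy(dtype=float)
    w = weights.loc[idx].to_numpy(dtype=float)
    fit = fit_logistic(X, y, weights=w)
    table = coefficient_table(fit, variance=variance)
    return PSWFit(
        table=table,
        fit=fit,
        retained_mask=retained_mask,
        weights=weights.loc[idx],
        n_model=len(idx),
        variance=variance,
    )


# ---------------------------------------------------------------------------
# diagnostics


def kde_scores(
    e: pd.Series,
    by,
    bandwidth="silverman",
    gridsize: int = 512,
) -> pd.DataFrame:
    """Gaussian-kernel density of propensity scores per period group.

    Evaluated on a common ``gridsize``-point grid spanning [0, 1] (the score
    scale).  A group with fewer than two distinct values cannot support a
    density estimate; its curve is returned as NaN and flagged in
    ``DataFrame.attrs['degenerate']``.
    """
    grid = np.linspace(0.0, 1.0, gridsize)
    out = pd.DataFrame({"score": grid})
    zv = np.asarray(by)
    degenerate = []
    for group in (0, 1):
        vals = np.asarray(e, dtype=float)[zv == group]
        col = f"density_{group}"
        if len(np.unique(vals)) < 2:
            out[col] = np.nan
            degenerate.append(group)
            continue
        kde = stats.gaussian_kde(vals, bw_method=bandwidth)
        out[col] = kde(grid)
    out.attrs["degenerate"] = degenerate
    return out


def plot_kde(curves: pd.DataFrame, path, labels=("earlier year", "later year")) -> None:
    """Render a score-overlap KDE plot to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curves["score"], curves["density_0"], label=labels[0])
    ax.plot(curves["score"], curves["density_1"], label=labels[1])
    ax.set_xlabel("propensity score")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def balance_smd(X: pd.DataFrame, z, weights=None) -> pd.Series:
    """Standardised mean difference per design column between the two periods.

    ``SMD = (mean1 - mean0) / sqrt((v1 + v0) / 2)`` with weighted means and
    variances when weights are supplied.  Columns with zero pooled variance
    report 0 when the means agree and NaN (flagged) otherwise.
    """
    zv = np.asarray(z, dtype=float)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        stats_by_group = []
        for g in (0, 1):
            sel = zv == g
            m = np.average(v[sel], weights=w[sel])
            var = np.average((v[sel] - m) ** 2, weights=w[sel])
            stats_by_group.append((m, var))
        (m0, v0), (m1, v1) = stats_by_group
        denom = np.sqrt((v0 + v1) / 2.0)
        if denom == 0.0:
            out[col] = 0.0 if np.isclose(m0, m1) else np.nan
        else:
            out[col] = (m1 - m0) / denom
    return pd.Series(out, name="smd")


def balance_report(X: pd.DataFrame, z, weights) -> pd.DataFrame:
    """Before/after-weighting SMD table, sorted by post-weighting imbalance."""
    before = balance_smd(X, z)
    after = balance_smd(X, z, weights)
    report = pd.DataFrame({"smd_unweighted": before, "smd_weighted": after})
    report = report.reindex(report["smd_weighted"].abs().sort_values(ascending=False).index)
    report.attrs["max_abs_smd_unweighted"] = float(before.abs().max())
    report.attrs["max_abs_smd_weighted"] = float(after.abs().max())
    return report
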