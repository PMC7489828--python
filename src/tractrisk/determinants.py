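"""Association of the tract excess-risk difference with social determinants.

Provides Pearson correlations, Bonferroni-screened univariate OLS of the
difference on each determinant, multivariate OLS with backward stepwise
elimination, and the mean-rank composite. Regressions are run on the
risk-fraction scale (per-100k difference / 1e5), the scale on which tract
regression slopes and residual SEs are conventionally reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ArgumentError, CollinearityError, ConfigError, StatisticError
from .excess import ExcessSummary

logger = logging.getLogger(__name__)

PER_100K = 100_000.0


def _difference_frac(summary) -> pd.Series:
    table = summary.table if isinstance(summary, ExcessSummary) else summary
    return pd.Series(
        table["difference_per_100k"].to_numpy() / PER_100K,
        index=pd.Index(table["tract_id"], name="tract_id"),
        name="difference",
    )


#: Named model presets mirroring the conventional column layout of a
#: tract-determinant regression table: income-based variables, income plus
#: education, tract disease-prevalence ("biological") variables, and the
#: combined social and biological model.
MODEL_PRESETS: dict[str, list[str]] = {
    "income": ["median_income", "food_stamps_pct", "no_jobs_pct",
               "poverty_index", "no_insurance_pct"],
    "income_education": ["median_income", "food_stamps_pct", "no_jobs_pct",
                         "hs_grad_pct"],
    "biological": ["diabetes_pct", "hypertension_pct", "hyperlipidemia_pct"],
    "combined": ["median_income", "food_stamps_pct", "no_jobs_pct",
                 "hs_grad_pct", "diabetes_pct", "hypertension_pct",
                 "hyperlipidemia_pct"],
}


def condition_prevalence_table(claims: pd.DataFrame,
                               demographics: pd.DataFrame) -> pd.DataFrame:
    """Tract disease-prevalence columns (percent of adults 20+) from claims.

    Turns insurer claim counts into the "biological" tract determinants:
    one ``<condition>_pct`` column per claimed condition.
    """
    from .bands import ADULT_BANDS
    adults = (demographics[demographics["age_band"].isin(ADULT_BANDS)]
              .groupby("tract_id")["count"].sum())
    wide = claims.pivot_table(index="tract_id", columns="condition",
                              values="count", aggfunc="sum", fill_value=0)
    out = pd.DataFrame({"tract_id": wide.index})
    for cond in wide.columns:
        denom = adults.reindex(wide.index)
        if denom.isna().any():
            missing = list(denom.index[denom.isna()])[:5]
            raise ArgumentError(f"no adult population for tract(s): {missing}")
        out[f"{cond}_pct"] = (100.0 * wide[cond] / denom.clip(lower=1)).to_numpy()
    return out


def pearson_correlation(x, y) -> tuple[float, float]:
    """Two-tailed Pearson correlation; p from the t transform with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ArgumentError("x and y must have equal length")
    if len(x) < 3:
        raise ArgumentError(f"need >= 3 observations, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatisticError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    slope: float
    ci95: tuple[float, float]
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: per-term slopes/CIs/p, fit diagnostics."""

    terms: tuple[RegressionTerm, ...]
    intercept: RegressionTerm
    r2: float
    adjusted_r2: float
    residual_se: float
    n: int

    def term(self, name: str) -> RegressionTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def summary(self) -> pd.DataFrame:
        rows = [self.intercept, *self.terms]
        return pd.DataFrame(
            {
                "slope": [t.slope for t in rows],
                "ci_low": [t.ci95[0] for t in rows],
                "ci_high": [t.ci95[1] for t in rows],
                "p_value": [t.p_value for t in rows],
            },
            index=[t.name for t in rows],
        )


def _ols(y: np.ndarray, X: pd.DataFrame) -> RegressionResult:
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise CollinearityError(list(X.columns))
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = []
    for name in design.columns:
        term = RegressionTerm(
            name=name,
            slope=float(fit.params[name]),
            ci95=(float(ci.loc[name, 0]), float(ci.loc[name, 1])),
            p_value=float(fit.pvalues[name]),
        )
        if name == "const":
            intercept = term
        else:
            terms.append(term)
    return RegressionResult(
        terms=tuple(terms),
        intercept=intercept,
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        residual_se=float(np.sqrt(fit.scale)),
        n=int(fit.nobs),
    )


def _aligned(summary, determinants: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    y = _difference_frac(summary)
    det = determinants.set_index("tract_id") if "tract_id" in determinants.columns \
        else determinants
    det = det.reindex(y.index)
    return y, det


@dataclass
class UnivariateScreen:
    """Per-determinant univariate OLS with a Bonferroni significance flag."""

    results: dict[str, RegressionResult]
    table: pd.DataFrame
    alpha: float
    m: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.m

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def univariate_screen(summary, determinants: pd.DataFrame,
                      alpha: float = 0.05) -> UnivariateScreen:
    """Simple linear regression of the difference on each determinant.

    Significance uses a Bonferroni-corrected threshold alpha/m, with m the
    number of determinants actually screened (all-missing columns are
    skipped with a warning; each fit is complete-case).
    """
    y, det = _aligned(summary, determinants)
    results: dict[str, RegressionResult] = {}
    for name in det.columns:
        x = det[name]
        mask = x.notna() & y.notna()
        if mask.sum() == 0:
            logger.warning("determinant %s: all values missing; skipped", name)
            continue
        if mask.sum() < 3:
            raise ArgumentError(f"determinant {name}: fewer than 3 complete cases")
        results[name] = _ols(y[mask].to_numpy(), x[mask].to_frame())
    if not results:
        raise ArgumentError("no determinant could be screened")
    m = len(results)
    thr = alpha / m
    rows = {
        name: {
            "slope": res.term(name).slope,
            "ci_low": res.term(name).ci95[0],
            "ci_high": res.term(name).ci95[1],
            "p_value": res.term(name).p_value,
            "n": res.n,
            "significant": res.term(name).p_value < thr,
        }
        for name, res in results.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return UnivariateScreen(results=results, table=table, alpha=alpha, m=m)


def multivariate_fit(summary, determinants: pd.DataFrame,
                     terms: list[str]) -> RegressionResult:
    """Multivariate OLS of the difference on the named determinants."""
    if not terms:
        raise ArgumentError("terms must be nonempty")
    y, det = _aligned(summary, determinants)
    missing = set(terms) - set(det.columns)
    if missing:
        raise ConfigError(f"unknown determinant term(s): {sorted(missing)}")
    X = det[list(terms)]
    mask = X.notna().all(axis=1) & y.notna()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("multivariate fit: %d incomplete case(s) dropped", dropped)
    if mask.sum() <= len(terms) + 1:
        raise ArgumentError("not enough complete cases for the requested terms")
    return _ols(y[mask].to_numpy(), X[mask])


def backward_stepwise(
    summary,
    determinants: pd.DataFrame,
    candidates: list[str],
    p_remove: float = 0.05,
) -> tuple[list[str], list[dict]]:
    """Backward elimination on p-values.

    Starting from the full candidate model, repeatedly drop the term with
    the highest p-value above ``p_remove`` (ties broken toward the term
    later in candidate order) and refit; stop when all retained terms have
    p <= p_remove or a single term remains. Returns the retained terms and
    a per-step trace (terms, adjusted R², dropped term and its p).
    """
    if not candidates:
        raise ArgumentError("candidates must be nonempty")
    retained = list(candidates)
    trace: list[dict] = []
    while True:
        fit = multivariate_fit(summary, determinants, retained)
        pvals = {t.name: t.p_value for t in fit.terms}
        over = [name for name in retained if pvals[name] > p_remove]
        step = {"terms": list(retained), "adjusted_r2": fit.adjusted_r2,
                "dropped": None, "dropped_p": None, "fit": fit}
        if not over or len(retained) == 1:
            trace.append(step)
            return retained, trace
        worst_p = max(pvals[name] for name in over)
        # later candidate order wins on exact ties
        worst = [name for name in retained if pvals[name] == worst_p][-1]
        step["dropped"] = worst
        step["dropped_p"] = worst_p
        trace.append(step)
        retained = [name for name in retained if name != worst]


@dataclass
class RankComposite:
    """Mean determinant rank per tract and its regression on the difference."""

    mean_rank: pd.Series
    ranks: pd.DataFrame
    regression: RegressionResult


def rank_composite(
    summary,
    determinants: pd.DataFrame,
    subset: list[str],
    orientation: dict[str, str],
) -> RankComposite:
    """Rank tracts per determinant (1 = most favorable), average, regress.

    Orientation decides the sort direction: "favorable_high" ranks the
    largest value 1, "favorable_low" the smallest. Ties receive average
    ranks. The composite is the mean rank across the subset; the attached
    regression is OLS of the difference on the mean rank.
    """
    if not subset:
        raise ArgumentError("subset must be nonempty")
    y, det = _aligned(summary, determinants)
    unknown = set(subset) - set(det.columns)
    if unknown:
        raise ConfigError(f"unknown determinant(s) in subset: {sorted(unknown)}")
    unoriented = [name for name in subset if name not in orientation]
    if unoriented:
        raise ConfigError(f"no orientation for determinant(s): {unoriented}")

    ranks = pd.DataFrame(index=det.index)
    for name in subset:
        asc = orientation[name] == "favorable_low"
        ranks[name] = det[name].rank(ascending=asc, method="average")
    mean_rank = ranks.mean(axis=1)
    mean_rank.name = "mean_rank"
    reg = _ols(y.to_numpy(), mean_rank.to_frame())
    return RankComposite(mean_rank=mean_rank, ranks=ranks, regression=reg)
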