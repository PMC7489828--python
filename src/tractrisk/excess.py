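"""Observed tract death risk, excess-risk difference and calibration.

Observed risk is the directly age-standardized 4-year CVD death rate per
100 000, applied to the tract population. The headline statistic is the
difference expected - observed per 100 000: negative values mean more
deaths occurred in the tract than the individual-level risk model predicts
(excess observed risk). A calibration regression of observed on expected
rates checks that the risk equation tracks reality (slope near 1,
intercept near 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
import statsmodels.api as sm

from .bands import AGE_BANDS, US2000_WEIGHTS
from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)

PER_100K = 100_000.0


@dataclass(frozen=True)
class StandardPopulation:
    """Age-band weights for direct standardization (must sum to 1)."""

    weights: dict[str, float]

    def __post_init__(self):
        if set(self.weights) - set(AGE_BANDS):
            raise ArgumentError("standard population has unknown age bands")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ArgumentError(f"standard weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ArgumentError("standard weights must be nonnegative")

    @classmethod
    def us2000(cls) -> "StandardPopulation":
        """The US 2000 standard-million age distribution."""
        return cls(weights=dict(US2000_WEIGHTS))


def age_adjusted_rate(
    deaths_by_band: dict[str, float] | pd.Series,
    population_by_band: dict[str, float] | pd.Series,
    standard: StandardPopulation,
) -> float:
    """Directly standardized death rate per 100 000 over the period.

    rate = 1e5 * sum_b w_b * deaths_b / pop_b. A band with zero population
    and zero deaths contributes zero at its full weight; deaths in a
    zero-population band are a data error.
    """
    deaths = dict(deaths_by_band)
    pops = dict(population_by_band)
    rate = 0.0
    for band, w in standard.weights.items():
        d = float(deaths.get(band, 0.0))
        p = float(pops.get(band, 0.0))
        if d < 0 or p < 0:
            raise DataError(f"negative deaths or population in band {band}")
        if p == 0:
            if d > 0:
                raise DataError(f"deaths recorded in zero-population band {band}")
            continue
        rate += w * d / p
    return PER_100K * rate


def observed_tract_deaths(rate_per_100k: float, tract_population: float) -> float:
    """Observed deaths implied by an age-adjusted rate: rate x population."""
    if rate_per_100k < 0 or tract_population < 0:
        raise ArgumentError("rate and population must be nonnegative")
    return rate_per_100k / PER_100K * tract_population


def tract_observed_rates(
    deaths: pd.DataFrame,
    demographics: pd.DataFrame,
    standard: StandardPopulation | None = None,
) -> pd.DataFrame:
    """Age-adjusted observed rate per tract from deaths-by-band counts."""
    standard = standard or StandardPopulation.us2000()
    pop = demographics.groupby(["tract_id", "age_band"])["count"].sum()
    dth = deaths.groupby(["tract_id", "age_band"])["deaths"].sum()
    rows = []
    for tid in sorted(deaths["tract_id"].unique()):
        d_b = dth.xs(tid, level="tract_id").to_dict()
        if tid not in pop.index.get_level_values("tract_id"):
            raise DataError(f"no demographics for tract {tid}")
        p_b = pop.xs(tid, level="tract_id").to_dict()
        rate = age_adjusted_rate(d_b, p_b, standard)
        total_pop = sum(p_b.values())
        rows.append((tid, rate, observed_tract_deaths(rate, total_pop)))
    return pd.DataFrame(rows, columns=["tract_id", "observed_per_100k", "observed_deaths"])


@dataclass
class ExcessSummary:
    """Per-tract expected/observed/difference table plus headline stats."""

    table: pd.DataFrame
    excluded: pd.DataFrame
    stats: dict

    def __len__(self):
        return len(self.table)


def risk_difference(
    expected: pd.DataFrame,
    observed: pd.DataFrame,
    min_population: int = 50,
) -> ExcessSummary:
    """Expected minus observed risk per 100 000, per tract.

    Negative differences mark tracts where observed deaths exceed the
    model's expectation (excess observed risk). Tracts below
    ``min_population`` are excluded from the analysis table and reported
    separately, mirroring small areas whose data are suppressed.
    """
    exp_ids = set(expected["tract_id"])
    obs_ids = set(observed["tract_id"])
    if exp_ids != obs_ids:
        odd = sorted(exp_ids.symmetric_difference(obs_ids))
        raise DataError(f"expected/observed tract ids do not match: {odd[:5]}")
    merged = expected.merge(observed, on="tract_id", validate="1:1")
    merged["difference_per_100k"] = (
        merged["expected_per_100k"] - merged["observed_per_100k"])

    small = merged["population"] < min_population
    if small.any():
        logger.warning("excluding %d tract(s) below minimum population %d",
                       int(small.sum()), min_population)
    table = merged.loc[~small].reset_index(drop=True)
    excluded = merged.loc[small].reset_index(drop=True)

    diff = table["difference_per_100k"]
    neg = diff < 0
    total_pop = int(table["population"].sum())
    stats = {
        "n_tracts": int(len(table)),
        "n_excluded": int(len(excluded)),
        "min": float(diff.min()) if len(table) else float("nan"),
        "max": float(diff.max()) if len(table) else float("nan"),
        "mean": float(diff.mean()) if len(table) else float("nan"),
        "sd": float(diff.std()) if len(table) else float("nan"),
        "n_negative": int(neg.sum()),
        "negative_population": int(table.loc[neg, "population"].sum()),
        "share_negative_population": (
            float(table.loc[neg, "population"].sum() / total_pop) if total_pop else 0.0),
    }
    return ExcessSummary(table=table, excluded=excluded, stats=stats)


@dataclass(frozen=True)
class CalibrationFit:
    """OLS of observed on expected risk (both as 4-year risk fractions)."""

    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    r_squared: float
    n: int

    @property
    def slope_covers_one(self) -> bool:
        return self.slope_ci95[0] <= 1.0 <= self.slope_ci95[1]

    @property
    def intercept_covers_zero(self) -> bool:
        return self.intercept_ci95[0] <= 0.0 <= self.intercept_ci95[1]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.intercept, self.slope],
                "ci_low": [self.intercept_ci95[0], self.slope_ci95[0]],
                "ci_high": [self.intercept_ci95[1], self.slope_ci95[1]],
            },
            index=["intercept", "slope"],
        )


def calibration_regression(summary: ExcessSummary | pd.DataFrame) -> CalibrationFit:
    """Regress observed on expected 4-year risk across tracts.

    Rates are converted to risk fractions (per-100k / 1e5) so the intercept
    is on the scale conventionally reported. A slope CI covering 1 and an
    intercept CI covering 0 indicate the risk equation gives an acceptable
    estimate of observed mortality.
    """
    table = summary.table if isinstance(summary, ExcessSummary) else summary
    if len(table) < 3:
        raise ArgumentError(f"calibration needs >= 3 tracts, got {len(table)}")
    x = table["expected_per_100k"].to_numpy() / PER_100K
    y = table["observed_per_100k"].to_numpy() / PER_100K
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return CalibrationFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci95=(float(ci[0][0]), float(ci[0][1])),
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
    )
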