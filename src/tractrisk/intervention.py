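"""Counterfactual determinant-improvement scenarios.

A scenario multiplies beneficial determinants up and harmful ones down by a
relative magnitude (10% or 20% in the motivating analysis), clamps
percentage columns to [0, 100], and applies special rules (e.g. high-school
graduation at 90% or higher jumps to 100%). Predicted tract differences
shift by fitted-coefficient x covariate change on top of each tract's
baseline difference, so unexplained tract residuals persist; the summary
counts how many tracts (and how much population) remain in excess risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .determinants import RegressionResult
from .errors import ConfigError, DataError
from .excess import ExcessSummary

PER_100K = 100_000.0


class SpecialRule(BaseModel):
    """If a tract's baseline value is >= threshold, set the modified value."""

    model_config = ConfigDict(frozen=True)
    determinant: str
    threshold: float
    set_to: float


class InterventionScenario(BaseModel):
    """A counterfactual change to tract determinant values.

    mode "relative" scales each value by (1 +/- magnitude); mode "points"
    adds/subtracts magnitude directly (for determinants already on a
    percentage-point scale). Columns named ``*_pct`` are always clamped to
    [0, 100]; additional (floor, ceiling) caps may be given per determinant.
    """

    model_config = ConfigDict(frozen=True)
    magnitude: float
    directions: dict[str, Literal["increase", "decrease"]]
    caps: dict[str, tuple[float, float]] = {}
    special_rules: tuple[SpecialRule, ...] = ()
    mode: Literal["relative", "points"] = "relative"

    @field_validator("magnitude")
    @classmethod
    def _check_magnitude(cls, v):
        if v <= 0:
            raise ConfigError(f"magnitude must be > 0, got {v}")
        return v

    @field_validator("directions")
    @classmethod
    def _check_directions(cls, v):
        if not v:
            raise ConfigError("scenario modifies no determinant")
        return v


def apply_scenario(determinants: pd.DataFrame,
                   scenario: InterventionScenario) -> pd.DataFrame:
    """Return the determinant table after the counterfactual change.

    Unmodified columns are returned identical. Order of operations per
    modified column: scale (or shift), cap/clamp, then special rules keyed
    on the baseline value.
    """
    unknown = set(scenario.directions) - set(determinants.columns)
    if unknown:
        raise ConfigError(f"scenario directs unknown determinant(s): {sorted(unknown)}")
    for rule in scenario.special_rules:
        if rule.determinant not in determinants.columns:
            raise ConfigError(f"special rule targets unknown determinant {rule.determinant!r}")

    out = determinants.copy()
    for name, direction in scenario.directions.items():
        sign = 1.0 if direction == "increase" else -1.0
        x = out[name].to_numpy(dtype=float)
        if scenario.mode == "relative":
            x = x * (1.0 + sign * scenario.magnitude)
        else:
            x = x + sign * scenario.magnitude
        if name.endswith("_pct"):
            x = np.clip(x, 0.0, 100.0)
        if name in scenario.caps:
            floor, ceiling = scenario.caps[name]
            x = np.clip(x, floor, ceiling)
        out[name] = x
    for rule in scenario.special_rules:
        baseline = determinants[rule.determinant].to_numpy(dtype=float)
        vals = out[rule.determinant].to_numpy(dtype=float)
        vals[baseline >= rule.threshold] = rule.set_to
        out[rule.determinant] = vals
    return out


def predict_difference(
    fit: RegressionResult,
    summary: ExcessSummary | pd.DataFrame,
    baseline: pd.DataFrame,
    modified: pd.DataFrame,
) -> pd.Series:
    """Per-tract predicted difference (per 100k) under the scenario.

    predicted = baseline difference + 1e5 * sum_j beta_j (x'_j - x_j); the
    fitted coefficients are on the risk-fraction scale. An identity
    scenario therefore reproduces the baseline exactly, and every tract
    keeps its unexplained residual.
    """
    table = summary.table if isinstance(summary, ExcessSummary) else summary
    base = baseline.set_index("tract_id") if "tract_id" in baseline.columns else baseline
    mod = modified.set_index("tract_id") if "tract_id" in modified.columns else modified
    idx = pd.Index(table["tract_id"])
    shift = np.zeros(len(table))
    for term in fit.terms:
        for df, label in ((base, "baseline"), (mod, "modified")):
            if term.name not in df.columns:
                raise DataError(f"term {term.name!r} missing from {label} determinant table")
        dx = mod[term.name].reindex(idx).to_numpy() - base[term.name].reindex(idx).to_numpy()
        if np.isnan(dx).any():
            raise DataError(f"term {term.name!r}: missing values for some tracts")
        shift += term.slope * dx
    pred = table["difference_per_100k"].to_numpy() + PER_100K * shift
    return pd.Series(pred, index=idx, name="predicted_difference_per_100k")


@dataclass(frozen=True)
class ScenarioResult:
    """Residual excess risk after a counterfactual scenario."""

    n_negative_tracts: int
    negative_tract_population: int
    share_of_total_population: float
    predicted: pd.Series

    def summary(self) -> str:
        return (f"{self.n_negative_tracts} tract(s) with negative difference, "
                f"population {self.negative_tract_population} "
                f"({100 * self.share_of_total_population:.0f}% of total)")


def summarize_scenario(predicted: pd.Series, populations: pd.Series) -> ScenarioResult:
    """Count tracts still in excess risk (predicted difference < 0)."""
    pops = populations.reindex(predicted.index)
    if pops.isna().any():
        raise DataError("populations missing for some predicted tracts")
    neg = predicted < 0
    total = float(pops.sum())
    neg_pop = int(pops[neg].sum())
    return ScenarioResult(
        n_negative_tracts=int(neg.sum()),
        negative_tract_population=neg_pop,
        share_of_total_population=neg_pop / total if total else 0.0,
        predicted=predicted,
    )
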