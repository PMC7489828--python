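"""Individual cardiovascular-death risk and tract-level expected risk.

The risk equation is a proportional-hazards survival form,

    risk_5yr = 1 - S0(sex, age band) ** exp(sum_j beta_j (x_j - c_j)),

with sex- and age-band-specific baseline 5-year survival S0 and centered
covariates (smoking, diabetes, systolic blood pressure, total cholesterol
by default). Persons aged 18 years or younger receive exactly zero risk.
Five-year risks are rescaled to the 4-year observation window and summed
over each census tract to give the expected death risk per 100 000.

The packaged default model is synthetic: its coefficients are plausible in
sign and magnitude but are NOT the published values of any specific risk
equation; supply your own model JSON for substantive work.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .bands import ADULT_AGE, AGE_BANDS
from .errors import ArgumentError, ConfigError

PER_100K = 100_000.0


class RiskModel(BaseModel):
    """Proportional-hazards CVD-death risk equation.

    baseline_survival maps sex -> age band -> 5-year baseline survival S0
    in (0, 1]; coefficients map person-table covariates to log-hazard-ratio
    slopes; centers give the covariate value at which the linear predictor
    is zero (flags center at 0).
    """

    model_config = ConfigDict(frozen=True)

    baseline_survival: dict[str, dict[str, float]]
    coefficients: dict[str, float]
    centers: dict[str, float]
    horizon_years: float = 5.0

    @field_validator("baseline_survival")
    @classmethod
    def _check_s0(cls, v):
        for sex, bands in v.items():
            for band, s0 in bands.items():
                if band not in AGE_BANDS:
                    raise ConfigError(f"unknown age band {band!r} in baseline_survival")
                if not 0.0 < s0 <= 1.0:
                    raise ConfigError(f"S0 must be in (0,1], got {s0} for ({sex}, {band})")
        return v

    @field_validator("horizon_years")
    @classmethod
    def _check_horizon(cls, v):
        if v <= 0:
            raise ConfigError(f"horizon_years must be positive, got {v}")
        return v

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def default(cls) -> "RiskModel":
        """The packaged synthetic default model (see module docstring)."""
        text = (importlib.resources.files("tractrisk") / "data" /
                "default_risk_model.json").read_text()
        return cls(**json.loads(text))


def _linear_predictor(persons: pd.DataFrame, model: RiskModel) -> np.ndarray:
    lp = np.zeros(len(persons))
    for name, beta in model.coefficients.items():
        if name not in persons.columns:
            raise ConfigError(f"model covariate {name!r} not found on person table")
        x = persons[name].to_numpy(dtype=float)
        lp += beta * (x - model.centers.get(name, 0.0))
    return lp


def risk_5yr(persons: pd.DataFrame, model: RiskModel) -> np.ndarray:
    """5-year CVD death risk per person; exactly 0 at age <= 18."""
    lut = {f"{sex}|{band}": s0
           for sex, bands in model.baseline_survival.items()
           for band, s0 in bands.items()}
    key = persons["sex"].astype(str) + "|" + persons["age_band"].astype(str)
    s0 = key.map(lut).to_numpy(dtype=float)
    if np.isnan(s0).any():
        bad = key[np.isnan(s0)].iloc[0]
        raise ConfigError(f"no baseline survival for stratum {bad!r}")
    risk = 1.0 - s0 ** np.exp(_linear_predictor(persons, model))
    risk[persons["age"].to_numpy(dtype=float) <= ADULT_AGE] = 0.0
    return risk


def scale_to_horizon(r: np.ndarray | float, target_years: float = 4.0,
                     horizon_years: float = 5.0, method: str = "hazard"):
    """Rescale a cumulative risk to a shorter horizon.

    "hazard" assumes a constant hazard over the horizon,
    1 - (1 - r)^(t/h); "linear" multiplies by t/h. The two agree to first
    order for small risks.
    """
    arr = np.asarray(r, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ArgumentError("risk must be in [0,1]")
    frac = target_years / horizon_years
    if method == "hazard":
        out = 1.0 - (1.0 - arr) ** frac
    elif method == "linear":
        out = arr * frac
    else:
        raise ArgumentError(f"unknown scaling method {method!r}")
    return float(out) if np.isscalar(r) else out


def expected_tract_risk(
    persons: pd.DataFrame,
    model: RiskModel,
    target_years: float = 4.0,
    scaling: str = "hazard",
) -> pd.DataFrame:
    """Sum 4-year individual risks per tract; normalize per 100 000 persons.

    The denominator is the full tract population including children. Tracts
    with zero population cannot appear (they contribute no persons); the sum
    over tracts of expected deaths equals the sum of individual risks
    exactly.
    """
    r4 = scale_to_horizon(risk_5yr(persons, model), target_years,
                          model.horizon_years, method=scaling)
    df = pd.DataFrame({"tract_id": persons["tract_id"], "r4": r4})
    g = df.groupby("tract_id", sort=True)["r4"].agg(["sum", "size"])
    out = pd.DataFrame({
        "tract_id": g.index,
        "expected_deaths": g["sum"].to_numpy(),
        "population": g["size"].to_numpy(dtype=int),
        "expected_per_100k": PER_100K * g["sum"].to_numpy() / g["size"].to_numpy(),
    }).reset_index(drop=True)
    return out
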