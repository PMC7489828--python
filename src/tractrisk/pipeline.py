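"""End-to-end orchestration of the excess-risk analysis.

Runs the stages in order — simulate inputs (or load them), build the
semisynthetic population, assign risk, compute the excess-risk surface,
test its spatial clustering, regress it on determinants, and evaluate
counterfactual improvement scenarios — writing every artifact with
provenance metadata. The whole run is a pure function of (inputs, config,
seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io
from .determinants import (
    MODEL_PRESETS,
    RegressionResult,
    UnivariateScreen,
    backward_stepwise,
    condition_prevalence_table,
    multivariate_fit,
    rank_composite,
    univariate_screen,
)
from .errors import PipelineStageError
from .excess import (
    CalibrationFit,
    ExcessSummary,
    StandardPopulation,
    calibration_regression,
    risk_difference,
    tract_observed_rates,
)
from .intervention import (
    InterventionScenario,
    ScenarioResult,
    SpecialRule,
    apply_scenario,
    predict_difference,
    summarize_scenario,
)
from .population import (
    assign_conditions,
    expand_cells,
    impute_from_donors,
)
from .risk import RiskModel, expected_tract_risk
from .spatial import MoranResult, build_weights, morans_permutation
from .synthetic import (
    GroundTruth,
    gen_claims,
    gen_demographics,
    gen_determinants,
    gen_observed_deaths,
    gen_survey_pool,
    gen_tract_lattice,
)

logger = logging.getLogger(__name__)

#: Default planted ground truth: effect sizes (risk-fraction per
#: determinant unit) in the magnitude range tract-level regressions report,
#: with tract-level noise giving a difference SD near 500 per 100k.
DEFAULT_EFFECTS = {
    "food_stamps_pct": -2e-4,
    "no_jobs_pct": -4e-4,
    "hs_grad_pct": 3e-4,
    "median_income": 1e-7,
    "diabetes_pct": -1e-4,
}

#: Orientation of the claims-derived disease-prevalence determinants.
BIOLOGICAL_ORIENTATIONS = {
    "diabetes_pct": "favorable_low",
    "hypertension_pct": "favorable_low",
    "hyperlipidemia_pct": "favorable_low",
}


class RunConfig(BaseModel):
    """Configuration for a full simulated pipeline run."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    rows: int = 10
    cols: int = 10
    mean_pop: float = 3400.0
    survey_n: int = 5000
    coverage_fraction: float = 0.8
    determinant_effects: dict[str, float] = DEFAULT_EFFECTS
    noise_sd: float = 0.003
    spatial_rho: float = 0.6
    min_tract_population: int = 50
    weight_scheme: str = "rook"
    n_permutations: int = 999
    scenario_magnitudes: tuple[float, ...] = (0.10, 0.20)
    risk_model_path: str | None = None
    out_dir: str | None = None


@dataclass
class PipelineResult:
    """Everything a full run produces, stage by stage."""

    config: RunConfig
    truth: GroundTruth
    tracts: list
    demographics: pd.DataFrame
    survey: pd.DataFrame
    claims: pd.DataFrame
    determinants: pd.DataFrame
    persons: pd.DataFrame
    expected: pd.DataFrame
    deaths: pd.DataFrame
    observed: pd.DataFrame
    excess: ExcessSummary
    calibration: CalibrationFit
    moran: MoranResult
    screen: UnivariateScreen
    stepwise_terms: list[str]
    stepwise_trace: list[dict]
    combined_fit: RegressionResult
    named_fits: dict[str, RegressionResult]
    rank: object
    scenarios: dict[float, ScenarioResult]


def default_scenario(magnitude: float) -> InterventionScenario:
    """The canonical improvement scenario on the default determinant set.

    Beneficial determinants (high-school graduation, median income) are
    increased; harmful ones (food stamps, joblessness) are decreased;
    high-school graduation at 90% or above jumps straight to 100%.
    """
    return InterventionScenario(
        magnitude=magnitude,
        directions={
            "hs_grad_pct": "increase",
            "median_income": "increase",
            "food_stamps_pct": "decrease",
            "no_jobs_pct": "decrease",
            "diabetes_pct": "decrease",
            "hypertension_pct": "decrease",
            "hyperlipidemia_pct": "decrease",
        },
        special_rules=(SpecialRule(determinant="hs_grad_pct", threshold=90.0, set_to=100.0),),
    )


def _stage(name):
    class _ctx:
        def __enter__(self):
            logger.info("stage %s ...", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _ctx()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute simulate -> build -> risk -> excess -> spatial -> regress ->
    intervene with seeds derived deterministically from config.seed."""
    s = config.seed
    truth = GroundTruth(
        determinant_effects=dict(config.determinant_effects),
        noise_sd=config.noise_sd,
        spatial_rho=config.spatial_rho,
        seed=s,
    )

    with _stage("simulate"):
        tracts = gen_tract_lattice(config.rows, config.cols, seed=s)
        demographics = gen_demographics(tracts, config.mean_pop, seed=s + 1)
        survey = gen_survey_pool(config.survey_n, seed=s + 2)
        claims = gen_claims(tracts, demographics, seed=s + 3)
        determinants = gen_determinants(tracts, spatial_rho=config.spatial_rho, seed=s + 4)
        # claims-derived disease prevalences join the determinant table as
        # the "biological" variables
        determinants = determinants.merge(
            condition_prevalence_table(claims, demographics), on="tract_id")

    with _stage("population"):
        persons = expand_cells(demographics, seed=s + 5)
        persons = assign_conditions(persons, claims, config.coverage_fraction, seed=s + 6)
        persons = impute_from_donors(persons, survey, seed=s + 7)

    with _stage("risk"):
        model = (RiskModel.from_json(config.risk_model_path)
                 if config.risk_model_path else RiskModel.default())
        expected = expected_tract_risk(persons, model)

    with _stage("excess"):
        deaths = gen_observed_deaths(expected, demographics, determinants, truth, seed=s + 8)
        observed = tract_observed_rates(deaths, demographics, StandardPopulation.us2000())
        excess = risk_difference(expected, observed, config.min_tract_population)
        calibration = calibration_regression(excess)

    with _stage("spatial"):
        kept = set(excess.table["tract_id"])
        kept_tracts = [t for t in tracts if t.tract_id in kept]
        w = build_weights(kept_tracts, scheme=config.weight_scheme)
        diff = excess.table.set_index("tract_id")["difference_per_100k"]
        moran = morans_permutation(diff, w, config.n_permutations, seed=s + 9)

    with _stage("regress"):
        screen = univariate_screen(excess, determinants)
        # under a null truth (no planted effects) fall back to the default
        # candidate set so the model stages still exercise
        candidates = list(truth.determinant_effects) or list(DEFAULT_EFFECTS)
        retained, trace = backward_stepwise(excess, determinants, candidates)
        combined_fit = multivariate_fit(excess, determinants, retained)
        named_fits = {
            name: multivariate_fit(excess, determinants, terms)
            for name, terms in MODEL_PRESETS.items()
            if set(terms) <= set(determinants.columns)
        }
        from .synthetic import default_orientations
        orientations = {**default_orientations(), **BIOLOGICAL_ORIENTATIONS}
        rank = rank_composite(excess, determinants, list(determinants.columns[1:]),
                              orientations)

    with _stage("intervene"):
        pops = excess.table.set_index("tract_id")["population"]
        scenarios = {}
        for mag in config.scenario_magnitudes:
            scn = default_scenario(mag)
            modified = apply_scenario(determinants, scn)
            pred = predict_difference(combined_fit, excess, determinants, modified)
            scenarios[mag] = summarize_scenario(pred, pops)

    result = PipelineResult(
        config=config, truth=truth, tracts=tracts, demographics=demographics,
        survey=survey, claims=claims, determinants=determinants, persons=persons,
        expected=expected, deaths=deaths, observed=observed, excess=excess,
        calibration=calibration, moran=moran, screen=screen,
        stepwise_terms=retained, stepwise_trace=trace, combined_fit=combined_fit,
        named_fits=named_fits, rank=rank, scenarios=scenarios,
    )
    if config.out_dir:
        write_artifacts(result, config.out_dir)
    return result


def _config_hash(config: RunConfig) -> str:
    # hash the scientific configuration only, not filesystem paths
    payload = config.model_dump()
    payload.pop("out_dir", None)
    payload.pop("risk_model_path", None)
    import json as _json
    return hashlib.sha256(_json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def write_artifacts(result: PipelineResult, out_dir) -> None:
    """Write every stage artifact with provenance (seed, config hash)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": result.config.seed, "config": _config_hash(result.config)}
    io.write_geojson(result.tracts, out / "tracts.geojson", **meta)
    io.write_table(result.demographics, out / "demographics.csv", stage="simulate", **meta)
    io.write_table(result.survey, out / "survey.csv", stage="simulate", **meta)
    io.write_table(result.claims, out / "claims.csv", stage="simulate", **meta)
    io.write_table(result.determinants, out / "determinants.csv", stage="simulate", **meta)
    result.truth.to_json(out / "truth.json")
    io.write_table(result.persons, out / "population.csv", stage="population", **meta)
    io.write_table(result.expected, out / "expected.csv", stage="risk", **meta)
    io.write_table(result.deaths, out / "deaths.csv", stage="excess", **meta)
    io.write_table(result.excess.table, out / "summary.csv", stage="excess", **meta)
    io.write_table(result.screen.table.reset_index(names="determinant"),
                   out / "univariate.csv", stage="regress", **meta)
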