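"""Synthetic input generation with known ground truth.

Every input the pipeline consumes — tract geography, demographic marginals,
survey donor pool, insurer claim counts, social-determinant tables and
death counts — can be generated here with a planted, serialized ground
truth. Death counts are constructed so that the tract-level difference
between expected and observed risk equals a known linear function of the
determinants plus zero-mean noise, which makes the downstream regressions
testable by parameter recovery.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .bands import ADULT_BANDS, AGE_BANDS, BAND_BOUNDS
from .errors import ArgumentError, DataError
from .population import CONDITIONS, Tract

PER_100K = 100_000.0


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated dataset.

    determinant_effects map determinant name to its slope on the
    expected-minus-observed difference, on the risk-fraction scale (the
    per-100k difference is 1e5 times larger). noise_sd is the SD of the
    tract-level noise added to the difference, also a risk fraction.
    spatial_rho in [0, 1) controls how strongly determinant values are
    smoothed across adjacent tracts.
    """

    determinant_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    spatial_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ArgumentError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.spatial_rho < 1.0:
            raise ArgumentError(f"spatial_rho must be in [0,1), got {self.spatial_rho}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def gen_tract_lattice(n_rows: int, n_cols: int, seed: int = 0) -> list[Tract]:
    """Rectangular lattice of unit-square tracts with rook adjacency.

    Stands in for a county's census-tract map; ids are row-major. The seed
    is accepted for interface uniformity (the lattice is deterministic).
    """
    if n_rows < 1 or n_cols < 1:
        raise ArgumentError(f"lattice dimensions must be positive, got {n_rows}x{n_cols}")
    if n_rows * n_cols < 2:
        raise ArgumentError("lattice must contain at least 2 tracts")

    def tid(r, c):
        return f"T{r * n_cols + c:04d}"

    tracts = []
    for r in range(n_rows):
        for c in range(n_cols):
            nbrs = [
                tid(r + dr, c + dc)
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                if 0 <= r + dr < n_rows and 0 <= c + dc < n_cols
            ]
            tracts.append(Tract(
                tract_id=tid(r, c),
                neighbors=frozenset(nbrs),
                geometry=box(c, -(r + 1), c + 1, -r),
            ))
    return tracts


# Five-year age-band proportions of a realistic county population
# (adult-heavy, thinning above 65), normalized to sum to 1.
_DEFAULT_BAND_W = {
    "0-4": 0.053, "5-9": 0.057, "10-14": 0.060, "15-19": 0.061,
    "20-24": 0.064, "25-29": 0.065, "30-34": 0.058, "35-39": 0.060,
    "40-44": 0.064, "45-49": 0.076, "50-54": 0.081, "55-59": 0.074,
    "60-64": 0.059, "65-69": 0.045, "70-74": 0.035, "75-79": 0.035,
    "80-84": 0.029, "85+": 0.025,
}
_s = sum(_DEFAULT_BAND_W.values())
DEFAULT_AGE_BAND_WEIGHTS: dict[str, float] = {b: v / _s for b, v in _DEFAULT_BAND_W.items()}


def gen_demographics(
    tracts: list[Tract],
    mean_pop: float = 3400.0,
    age_band_weights: dict[str, float] | None = None,
    pct_male: float = 0.476,
    seed: int = 0,
    age_tilt_sd: float = 0.30,
    sex_logit_sd: float = 0.25,
) -> pd.DataFrame:
    """Demographic marginal cells (tract x age band x sex).

    Tract totals are Poisson(mean_pop); each total is split multinomially
    across the 36 (band, sex) cells. Tracts are heterogeneous, as real
    census tracts are: each tract tilts the age-band weights exponentially
    (weight_b proportional to w_b * exp(g * (mid_b - 42)/25) with
    g ~ N(0, age_tilt_sd), producing young student-heavy and old
    retirement-heavy tracts) and jitters the sex split on the logit scale.
    Degenerate inputs (a 0/1 sex share, single-band weights) are preserved
    exactly. Set both SDs to 0 for identically distributed tracts.
    """
    if mean_pop <= 0:
        raise ArgumentError(f"mean_pop must be positive, got {mean_pop}")
    if not 0.0 <= pct_male <= 1.0:
        raise ArgumentError(f"pct_male must be in [0,1], got {pct_male}")
    weights = dict(age_band_weights) if age_band_weights is not None else DEFAULT_AGE_BAND_WEIGHTS
    if set(weights) != set(AGE_BANDS):
        raise ArgumentError("age_band_weights must cover exactly the 18 five-year bands")
    w = np.array([weights[b] for b in AGE_BANDS], dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ArgumentError("age_band_weights must be a simplex (nonnegative, sum 1)")

    rng = np.random.default_rng(seed)
    mids = np.array([0.5 * sum(BAND_BOUNDS[b]) for b in AGE_BANDS])
    sexes = ["male"] * len(AGE_BANDS) + ["female"] * len(AGE_BANDS)
    bands = list(AGE_BANDS) * 2
    rows = []
    for t in tracts:
        tilt = rng.normal(0.0, age_tilt_sd) if age_tilt_sd > 0 else 0.0
        w_t = w * np.exp(tilt * (mids - 42.0) / 25.0)
        w_t /= w_t.sum()
        if 0.0 < pct_male < 1.0 and sex_logit_sd > 0:
            logit = np.log(pct_male / (1.0 - pct_male)) + rng.normal(0.0, sex_logit_sd)
            male_t = 1.0 / (1.0 + np.exp(-logit))
        else:
            male_t = pct_male
        probs = np.concatenate([w_t * male_t, w_t * (1.0 - male_t)])
        total = rng.poisson(mean_pop)
        counts = rng.multinomial(total, probs)
        for band, sex, cnt in zip(bands, sexes, counts):
            rows.append((t.tract_id, band, sex, int(cnt)))
    return pd.DataFrame(rows, columns=["tract_id", "age_band", "sex", "count"])


@dataclass(frozen=True)
class SurveyConfig:
    """Marginal distributions of the synthetic survey donor pool.

    Continuous biomarkers are normal around an age-adjusted mean (the age
    trend is centered at the pool's mean age, so the configured value stays
    the marginal mean); condition prevalences are age-tilted but scale
    multiplicatively, so a configured prevalence of 0 yields no cases.
    Defaults sit near familiar US adult population means (total cholesterol
    ~189 mg/dL, SBP ~122 mm Hg, HDL-C ~52 mg/dL).
    """

    age_min: float = 20.0
    age_max: float = 85.0
    sbp_mean: float = 122.0
    sbp_sd: float = 14.0
    sbp_age_slope: float = 0.35       # mm Hg per year of age
    chol_mean: float = 189.0
    chol_sd: float = 35.0
    chol_age_slope: float = 0.2
    hdl_mean: float = 52.0
    hdl_sd: float = 13.0
    hdl_female_shift: float = 8.0
    smoking_prev: float = 0.16
    diabetes_prev: float = 0.12
    hypertension_prev: float = 0.30
    hyperlipidemia_prev: float = 0.28
    pct_male: float = 0.48


def gen_survey_pool(n: int, seed: int = 0, config: SurveyConfig | None = None) -> pd.DataFrame:
    """Synthetic survey donor records with age/sex-dependent biomarkers."""
    if n < 1:
        raise ArgumentError(f"n must be >= 1, got {n}")
    cfg = config or SurveyConfig()
    rng = np.random.default_rng(seed)
    age = rng.uniform(cfg.age_min, cfg.age_max, size=n)
    mid = 0.5 * (cfg.age_min + cfg.age_max)
    sex = np.where(rng.random(n) < cfg.pct_male, "male", "female")

    sbp = rng.normal(cfg.sbp_mean + cfg.sbp_age_slope * (age - mid), cfg.sbp_sd)
    chol = rng.normal(cfg.chol_mean + cfg.chol_age_slope * (age - mid), cfg.chol_sd)
    hdl = rng.normal(cfg.hdl_mean + np.where(sex == "female", cfg.hdl_female_shift / 2,
                                             -cfg.hdl_female_shift / 2), cfg.hdl_sd)
    sbp = np.clip(sbp, 70.0, None)
    chol = np.clip(chol, 80.0, None)
    hdl = np.clip(hdl, 15.0, None)

    age_factor = np.clip(age / mid, 0.2, 2.0)           # chronic disease rises with age
    youth_factor = np.clip(2.0 - age / mid, 0.2, 2.0)   # smoking skews younger

    def bernoulli(p):
        return rng.random(n) < np.clip(p, 0.0, 1.0)

    return pd.DataFrame({
        "age": age,
        "sex": sex,
        "smoking": bernoulli(cfg.smoking_prev * youth_factor),
        "diabetes": bernoulli(cfg.diabetes_prev * age_factor),
        "hypertension": bernoulli(cfg.hypertension_prev * age_factor),
        "hyperlipidemia": bernoulli(cfg.hyperlipidemia_prev * age_factor),
        "sbp": sbp,
        "total_chol": chol,
        "hdl": hdl,
    })


DEFAULT_CONDITION_PREVALENCES = {
    "diabetes": 0.15,
    "hypertension": 0.32,
    "hyperlipidemia": 0.30,
}


def gen_claims(
    tracts: list[Tract],
    demographics: pd.DataFrame,
    condition_prevalences: dict[str, float] | None = None,
    seed: int = 0,
    prevalence_logit_sd: float = 0.6,
) -> pd.DataFrame:
    """Insurer-style tract claim counts per chronic condition.

    Counts are Binomial(adults aged 20+, p_t) per tract, where the tract
    prevalence p_t jitters the configured prevalence on the logit scale
    with SD ``prevalence_logit_sd`` — real tract disease burdens vary
    severalfold across a county. Degenerate prevalences are preserved: 1
    yields exactly the adult population and 0 yields zero in every tract;
    set the SD to 0 for a homogeneous county.
    """
    prev = dict(condition_prevalences) if condition_prevalences is not None \
        else DEFAULT_CONDITION_PREVALENCES
    for cond, p in prev.items():
        if cond not in CONDITIONS:
            raise ArgumentError(f"unknown condition {cond!r}")
        if not 0.0 <= p <= 1.0:
            raise ArgumentError(f"prevalence for {cond} must be in [0,1], got {p}")
    rng = np.random.default_rng(seed)
    adults = (
        demographics[demographics["age_band"].isin(ADULT_BANDS)]
        .groupby("tract_id")["count"].sum()
    )
    rows = []
    for t in tracts:
        n_adult = int(adults.get(t.tract_id, 0))
        for cond, p in prev.items():
            if 0.0 < p < 1.0 and prevalence_logit_sd > 0:
                logit = np.log(p / (1.0 - p)) + rng.normal(0.0, prevalence_logit_sd)
                p_t = 1.0 / (1.0 + np.exp(-logit))
            else:
                p_t = p
            rows.append((t.tract_id, cond, int(rng.binomial(n_adult, p_t))))
    return pd.DataFrame(rows, columns=["tract_id", "condition", "count"])


@dataclass(frozen=True)
class DeterminantSpec:
    """Marginal distribution and orientation of one social determinant."""

    name: str
    mean: float
    sd: float
    lower: float
    upper: float
    orientation: str  # "favorable_high" or "favorable_low"

    def __post_init__(self):
        if self.orientation not in ("favorable_high", "favorable_low"):
            raise ArgumentError(f"bad orientation {self.orientation!r} for {self.name}")


#: Tract-level social determinants emulating a county open-data portfolio:
#: income, education, employment, insurance, housing and food access.
DEFAULT_DETERMINANTS: tuple[DeterminantSpec, ...] = (
    DeterminantSpec("food_stamps_pct", 15.0, 10.0, 0.0, 80.0, "favorable_low"),
    DeterminantSpec("median_income", 55_000.0, 16_000.0, 15_000.0, 220_000.0, "favorable_high"),
    DeterminantSpec("hs_grad_pct", 88.0, 8.0, 40.0, 100.0, "favorable_high"),
    DeterminantSpec("college_pct", 32.0, 15.0, 2.0, 95.0, "favorable_high"),
    DeterminantSpec("no_jobs_pct", 8.0, 5.0, 0.0, 50.0, "favorable_low"),
    DeterminantSpec("no_insurance_pct", 10.0, 5.0, 0.0, 50.0, "favorable_low"),
    DeterminantSpec("poverty_index", 30.0, 15.0, 0.0, 100.0, "favorable_low"),
    DeterminantSpec("obesity_pct", 30.0, 8.0, 5.0, 60.0, "favorable_low"),
    DeterminantSpec("no_vehicle_pct", 12.0, 8.0, 0.0, 70.0, "favorable_low"),
    DeterminantSpec("vacant_houses_pct", 8.0, 5.0, 0.0, 50.0, "favorable_low"),
)


def default_orientations() -> dict[str, str]:
    return {s.name: s.orientation for s in DEFAULT_DETERMINANTS}


def gen_determinants(
    tracts: list[Tract],
    specs: tuple[DeterminantSpec, ...] | None = None,
    spatial_rho: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Spatially autocorrelated tract determinant table (one row per tract).

    Each determinant starts as i.i.d. standard normal noise per tract; the
    spatially correlated field mixes each tract's own noise (weight
    1 - spatial_rho) with the average noise of its rook neighbors (weight
    spatial_rho), is re-standardized, then shifted/scaled to the spec's
    mean/sd and clipped to its support. rho > 0 gives Moran's I a signal.
    """
    if not 0.0 <= spatial_rho < 1.0:
        raise ArgumentError(f"spatial_rho must be in [0,1), got {spatial_rho}")
    specs = specs or DEFAULT_DETERMINANTS
    rng = np.random.default_rng(seed)
    ids = [t.tract_id for t in tracts]
    index = {tid: i for i, tid in enumerate(ids)}
    nbr_idx = [[index[n] for n in t.neighbors] for t in tracts]

    out = {"tract_id": ids}
    for spec in specs:
        e = rng.standard_normal(len(ids))
        if spatial_rho > 0:
            nbr_mean = np.array([e[nb].mean() if nb else 0.0 for nb in nbr_idx])
            x = (1.0 - spatial_rho) * e + spatial_rho * nbr_mean
        else:
            x = e
        x = (x - x.mean()) / x.std() if x.std() > 0 else x
        out[spec.name] = np.clip(spec.mean + spec.sd * x, spec.lower, spec.upper)
    return pd.DataFrame(out)


def gen_observed_deaths(
    tract_expected: pd.DataFrame,
    demographics: pd.DataFrame,
    determinants: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    integer_counts: bool = True,
    binomial: bool = False,
    center_determinants: bool = True,
    standard_weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Tract death counts by age band with a planted difference structure.

    For each tract, the target observed rate (per 100k, 4-year window) is
    the expected rate minus the planted difference
    sum(effect_d * determinant_d) + Normal(0, noise_sd), converted to the
    per-100k scale and floored at 0. By default each determinant is
    mean-centered across tracts before the effects are applied, which keeps
    the planted difference surface centered near zero (so observed rates
    stay positive) without changing the recoverable slopes. Deaths are
    spread over age bands at a uniform rate (so direct age standardization
    recovers the target rate exactly before integerization). Integer counts
    (the default) use compensated rounding: band counts are floored and
    then incremented greedily wherever that shrinks the tract's
    standardized-rate error under ``standard_weights`` (default: the US
    2000 standard the analysis side also defaults to), which keeps the
    realized rate within half a death of the target. ``binomial=True``
    draws stochastic counts instead; ``integer_counts=False`` keeps exact
    real-valued counts.
    """
    from .bands import US2000_WEIGHTS
    required = {"tract_id", "expected_per_100k"}
    if not required <= set(tract_expected.columns):
        raise DataError(f"tract_expected must have columns {sorted(required)}")
    det = determinants.set_index("tract_id")
    missing_eff = set(truth.determinant_effects) - set(det.columns)
    if missing_eff:
        raise DataError(f"effects reference unknown determinant(s): {sorted(missing_eff)}")
    missing_tracts = set(tract_expected["tract_id"]) - set(det.index)
    if missing_tracts:
        raise DataError(
            f"determinant table missing tract(s): {sorted(missing_tracts)[:5]}")

    rng = np.random.default_rng(seed)
    pops = demographics.pivot_table(
        index="tract_id", columns="age_band", values="count", aggfunc="sum", fill_value=0)
    centers = {
        name: (det[name].mean() if center_determinants else 0.0)
        for name in truth.determinant_effects
    }

    rows = []
    for _, rec in tract_expected.iterrows():
        tid = rec["tract_id"]
        planted = sum(
            beta * (det.at[tid, name] - centers[name])
            for name, beta in truth.determinant_effects.items()
        )
        planted += rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
        target_rate = max(rec["expected_per_100k"] - PER_100K * planted, 0.0)
        pop_b = np.array([
            int(pops.at[tid, band]) if band in pops.columns else 0 for band in AGE_BANDS
        ])
        lam = target_rate / PER_100K * pop_b
        if binomial:
            d = rng.binomial(pop_b, min(target_rate / PER_100K, 1.0)).astype(float)
        elif integer_counts:
            w = np.array([(standard_weights or US2000_WEIGHTS).get(b, 0.0)
                          for b in AGE_BANDS])
            d = np.floor(lam)
            with np.errstate(divide="ignore", invalid="ignore"):
                inc = np.where(pop_b > 0, PER_100K * w / np.maximum(pop_b, 1), 0.0)
            # realized minus achievable standardized rate; zero-population
            # bands drop out of the standardization on both sides
            err = float(np.sum(inc * d) - np.sum(w[pop_b > 0]) * target_rate)
            for b in np.argsort(-(lam - d)):
                if pop_b[b] > 0 and abs(err + inc[b]) < abs(err):
                    d[b] += 1
                    err += inc[b]
        else:
            d = lam
        rows.extend(zip([tid] * len(AGE_BANDS), AGE_BANDS, d.astype(float)))
    return pd.DataFrame(rows, columns=["tract_id", "age_band", "deaths"])
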