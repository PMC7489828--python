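import numpy as np
import pandas as pd
import pytest

from tractrisk import (
    RiskModel,
    gen_claims,
    gen_demographics,
    gen_survey_pool,
    gen_tract_lattice,
)
from tractrisk.population import assign_conditions, expand_cells, impute_from_donors


@pytest.fixture(scope="session")
def lattice_3x3():
    return gen_tract_lattice(3, 3, seed=1)


@pytest.fixture(scope="session")
def lattice_6x6():
    return gen_tract_lattice(6, 6, seed=1)


@pytest.fixture(scope="session")
def small_inputs(lattice_6x6):
    """Demographics, survey pool and claims for a 36-tract toy county."""
    demo = gen_demographics(lattice_6x6, mean_pop=1200, seed=2)
    survey = gen_survey_pool(2000, seed=3)
    claims = gen_claims(lattice_6x6, demo, seed=4)
    return demo, survey, claims


@pytest.fixture(scope="session")
def small_population(small_inputs):
    demo, survey, claims = small_inputs
    persons = expand_cells(demo, seed=5)
    persons = assign_conditions(persons, claims, coverage_fraction=0.8, seed=6)
    return impute_from_donors(persons, survey, seed=7)


@pytest.fixture(scope="session")
def default_model():
    return RiskModel.default()


def make_persons(records):
    """Small person table from (tract, age, sex, flags/biomarker) dicts."""
    defaults = dict(smoking=False, diabetes=False, hypertension=False,
                    hyperlipidemia=False, sbp=120.0, total_chol=190.0,
                    hdl=52.0, claims_covered=False)
    rows = []
    for i, rec in enumerate(records):
        row = {"person_id": i, **defaults, **rec}
        from tractrisk.bands import band_of_age
        row.setdefault("age_band", band_of_age(row["age"])[0])
        rows.append(row)
    return pd.DataFrame(rows)


def flat_model(s0=0.95, coefficients=None, centers=None):
    """Risk model with one constant baseline survival across all strata."""
    from tractrisk.bands import AGE_BANDS
    bs = {sex: {b: s0 for b in AGE_BANDS} for sex in ("male", "female")}
    return RiskModel(baseline_survival=bs,
                     coefficients=coefficients or {},
                     centers=centers or {})


def ols_oracle(y, X):
    """Normal-equations OLS with t-based 95% CIs; independent of statsmodels.

    Returns (beta, ci_low, ci_high, p) arrays over [intercept, slopes].
    """
    from scipy import stats
    X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    return beta, beta - tcrit * se, beta + tcrit * se, p
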