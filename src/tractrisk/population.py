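"""Semisynthetic individual-level population construction.

Builds persons from census-tract demographic marginals, assigns chronic
conditions from tract-level insurer claim counts, and fills biomarkers and
behaviors by hot-deck imputation against a survey donor pool. The result is
a population with demographically reasonable, personally non-identifiable
values for every variable the cardiovascular risk equation needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import ADULT_AGE, AGE_BANDS, BAND_BOUNDS, band_of_age
from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)

CONDITIONS = ("diabetes", "hypertension", "hyperlipidemia")

#: Columns of the canonical person table, in order.
PERSON_COLUMNS = (
    "person_id", "tract_id", "age", "age_band", "sex",
    "smoking", "diabetes", "hypertension", "hyperlipidemia",
    "sbp", "total_chol", "hdl", "claims_covered",
)

SURVEY_COLUMNS = (
    "age", "sex", "smoking", "diabetes", "hypertension", "hyperlipidemia",
    "sbp", "total_chol", "hdl",
)


@dataclass(frozen=True)
class Tract:
    """A census tract: the spatial unit of the whole analysis.

    ``neighbors`` is the rook-contiguity relation (shared edge); it must be
    symmetric and never contain the tract itself. ``geometry`` is an optional
    shapely polygon used for GeoJSON output and queen contiguity.
    """

    tract_id: str
    neighbors: frozenset[str] = field(default_factory=frozenset)
    geometry: object | None = None

    def __post_init__(self):
        if self.tract_id in self.neighbors:
            raise DataError(f"tract {self.tract_id} lists itself as a neighbor")


def validate_tracts(tracts: list[Tract]) -> dict[str, Tract]:
    """Check id uniqueness and neighbor symmetry; return an id->Tract map."""
    by_id = {}
    for t in tracts:
        if t.tract_id in by_id:
            raise DataError(f"duplicate tract_id {t.tract_id}")
        by_id[t.tract_id] = t
    for t in tracts:
        for nb in t.neighbors:
            if nb not in by_id:
                raise DataError(f"tract {t.tract_id} references unknown neighbor {nb}")
            if t.tract_id not in by_id[nb].neighbors:
                raise DataError(
                    f"adjacency not symmetric: {t.tract_id}->{nb} but not back")
    return by_id


def _validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    required = {"tract_id", "age_band", "sex", "count"}
    missing = required - set(cells.columns)
    if missing:
        raise DataError(f"demographic cell table missing columns: {sorted(missing)}")
    bad = set(cells["age_band"]) - set(AGE_BANDS)
    if bad:
        raise DataError(f"unknown age band label(s): {sorted(bad)}")
    if (cells["count"] < 0).any():
        raise DataError("negative cell count")
    if cells.duplicated(["tract_id", "age_band", "sex"]).any():
        raise DataError("duplicate (tract_id, age_band, sex) cell")
    return cells


def expand_cells(cells: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Expand demographic marginal cells into one row per person.

    Each cell (tract, age band, sex, count) yields exactly ``count`` persons
    whose exact ages are drawn uniformly within the band (85+ is sampled
    uniformly on [85, 100)). Person counts are conserved exactly.
    """
    cells = _validate_cells(cells)
    rng = np.random.default_rng(seed)
    counts = cells["count"].to_numpy(dtype=np.int64)
    reps = np.repeat(np.arange(len(cells)), counts)
    tract = cells["tract_id"].to_numpy(dtype=object)[reps]
    band = cells["age_band"].to_numpy(dtype=object)[reps]
    sex = cells["sex"].to_numpy(dtype=object)[reps]
    lo = np.array([BAND_BOUNDS[b][0] for b in band])
    hi = np.array([BAND_BOUNDS[b][1] for b in band])
    age = rng.uniform(lo, hi) if len(band) else np.empty(0)
    persons = pd.DataFrame({
        "person_id": np.arange(len(band), dtype=np.int64),
        "tract_id": tract,
        "age": age,
        "age_band": band,
        "sex": sex,
    })
    for cond in ("smoking",) + CONDITIONS:
        persons[cond] = False
    for col in ("sbp", "total_chol", "hdl"):
        persons[col] = np.nan
    persons["claims_covered"] = False
    return persons


def assign_conditions(
    persons: pd.DataFrame,
    claims: pd.DataFrame,
    coverage_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign claimed chronic conditions to a claims-covered adult subset.

    Within each tract, ``round(coverage_fraction * n_adults)`` adults are
    marked as covered by insurer claims data; for each condition, exactly
    ``min(claim count, covered subset size)`` covered adults are flagged
    (counts exceeding the subset are clipped with a warning). Persons aged
    18 or younger are never flagged. Uncovered adults receive their
    condition flags later from a matched survey donor.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ArgumentError(f"coverage_fraction must be in [0,1], got {coverage_fraction}")
    known = set(persons["tract_id"].unique())
    unknown = set(claims["tract_id"]) - known
    if unknown:
        raise DataError(f"claims reference unknown tract(s): {sorted(unknown)[:5]}")
    bad_cond = set(claims["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise DataError(f"unknown condition(s) in claims: {sorted(bad_cond)}")
    if (claims["count"] < 0).any():
        raise DataError("negative claims count")

    rng = np.random.default_rng(seed)
    out = persons.copy()
    covered = np.zeros(len(out), dtype=bool)
    flags = {c: out[c].to_numpy().copy() for c in CONDITIONS}
    adult_mask = out["age"].to_numpy() > ADULT_AGE
    tract_codes, tract_ids = pd.factorize(out["tract_id"])
    claims_by_tract = {
        tid: dict(zip(g["condition"], g["count"]))
        for tid, g in claims.groupby("tract_id")
    }
    for code, tid in enumerate(tract_ids):
        adults = np.flatnonzero((tract_codes == code) & adult_mask)
        n_cov = int(round(coverage_fraction * len(adults)))
        cov_idx = rng.choice(adults, size=n_cov, replace=False) if n_cov else np.empty(0, int)
        covered[cov_idx] = True
        for cond, cnt in claims_by_tract.get(tid, {}).items():
            cnt = int(cnt)
            if cnt > n_cov:
                logger.warning(
                    "tract %s: %s claim count %d exceeds %d covered adults; clipped",
                    tid, cond, cnt, n_cov)
                cnt = n_cov
            if cnt:
                chosen = rng.choice(cov_idx, size=cnt, replace=False)
                flags[cond][chosen] = True
    out["claims_covered"] = covered
    for c in CONDITIONS:
        out[c] = flags[c]
    return out


def _donor_strata(pool: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    bands = band_of_age(pool["age"].to_numpy())
    strata: dict[tuple[str, str], list[int]] = {}
    for i, (sex, band) in enumerate(zip(pool["sex"], bands)):
        strata.setdefault((sex, band), []).append(i)
    return {k: np.asarray(v) for k, v in strata.items()}


def _candidate_strata(sex: str, band: str) -> list[list[tuple[str, str]]]:
    """Fallback ladder: exact (sex, band); (sex, adjacent band); sex only."""
    bi = AGE_BANDS.index(band)
    adjacent = [AGE_BANDS[j] for j in (bi - 1, bi + 1) if 0 <= j < len(AGE_BANDS)]
    return [
        [(sex, band)],
        [(sex, b) for b in adjacent],
        [(sex, b) for b in AGE_BANDS],
    ]


def impute_from_donors(
    persons: pd.DataFrame, pool: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Hot-deck imputation of biomarkers/behaviors from a survey donor pool.

    Every person is matched to a donor agreeing on sex and five-year age
    band, widening to adjacent bands and then to sex only when a stratum is
    empty (widened matches are logged). Systolic blood pressure, total and
    HDL cholesterol and smoking status are copied from the donor for
    everyone; condition flags are copied only for persons not covered by
    claims data — claimed conditions always take precedence over the donor's.
    """
    if pool is None or len(pool) == 0:
        raise ArgumentError("donor pool is empty")
    missing = set(SURVEY_COLUMNS) - set(pool.columns)
    if missing:
        raise DataError(f"survey pool missing columns: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    strata = _donor_strata(pool)
    out = persons.copy()
    donor_of = np.empty(len(out), dtype=np.int64)
    n_widened = 0

    sexes = out["sex"].to_numpy(dtype=object)
    bands = out["age_band"].to_numpy(dtype=object)
    # group persons by (sex, band) so each stratum is sampled vectorized
    keys = pd.MultiIndex.from_arrays([sexes, bands])
    for (sex, band), idx in pd.Series(np.arange(len(out)), index=keys).groupby(level=[0, 1]):
        members = idx.to_numpy()
        chosen_pool = None
        for level, candidates in enumerate(_candidate_strata(sex, band)):
            pools = [strata[k] for k in candidates if k in strata]
            if pools:
                chosen_pool = np.concatenate(pools)
                if level > 0:
                    n_widened += len(members)
                    logger.info(
                        "stratum (%s, %s): no exact donor, widened to level %d",
                        sex, band, level)
                break
        if chosen_pool is None:
            raise DataError(f"no donor available for sex {sex!r} at any widening level")
        donor_of[members] = rng.choice(chosen_pool, size=len(members), replace=True)

    if n_widened:
        logger.info("donor matching widened beyond exact stratum for %d persons", n_widened)

    for col in ("sbp", "total_chol", "hdl"):
        out[col] = pool[col].to_numpy()[donor_of]
    out["smoking"] = pool["smoking"].to_numpy().astype(bool)[donor_of]
    uncovered = ~out["claims_covered"].to_numpy()
    for cond in CONDITIONS:
        vals = out[cond].to_numpy().copy()
        vals[uncovered] = pool[cond].to_numpy().astype(bool)[donor_of[uncovered]]
        out[cond] = vals
    return out


@dataclass
class PopulationSummary:
    """Tract-range and whole-population characteristics of the built cohort."""

    per_tract: pd.DataFrame
    overall: pd.Series

    def table(self) -> pd.DataFrame:
        """Characteristic x (tract min, tract max, tract mean, tract SD, overall)."""
        stats = self.per_tract.agg(["min", "max", "mean", "std"]).T
        stats.columns = ["tract_min", "tract_max", "tract_mean", "tract_sd"]
        stats["overall"] = self.overall
        return stats


def summarize_population(persons: pd.DataFrame) -> PopulationSummary:
    """Per-tract ranges with mean (SD) across tracts, plus overall means."""
    if len(persons) == 0:
        raise ArgumentError("population is empty")

    def _stats(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "mean_age": g["age"].mean(),
            "pct_male": 100.0 * (g["sex"] == "male").mean(),
            "pct_smoker": 100.0 * g["smoking"].mean(),
            "pct_diabetes": 100.0 * g["diabetes"].mean(),
            "mean_total_chol": g["total_chol"].mean(),
            "mean_sbp": g["sbp"].mean(),
            "mean_hdl": g["hdl"].mean(),
        })

    per_tract = persons.groupby("tract_id", sort=True).apply(_stats, include_groups=False)
    overall = _stats(persons)
    return PopulationSummary(per_tract=per_tract, overall=overall)
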