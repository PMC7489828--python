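"""Generators: lattice combinatorics, marginals, claims, planted deaths."""

import numpy as np
import pandas as pd
import pytest

from tractrisk import (
    ArgumentError,
    DataError,
    GroundTruth,
    StandardPopulation,
    gen_claims,
    gen_demographics,
    gen_determinants,
    gen_observed_deaths,
    gen_survey_pool,
    gen_tract_lattice,
    tract_observed_rates,
)
from tractrisk.bands import ADULT_BANDS, AGE_BANDS
from tractrisk.population import validate_tracts
from tractrisk.synthetic import DEFAULT_AGE_BAND_WEIGHTS, SurveyConfig


class TestLattice:
    def test_corner_tracts_have_two_neighbors(self):
        tracts = gen_tract_lattice(3, 3, seed=1)
        assert len(tracts) == 9
        degrees = sorted(len(t.neighbors) for t in tracts)
        assert degrees == [2, 2, 2, 2, 3, 3, 3, 3, 4]
        validate_tracts(tracts)  # symmetry and uniqueness

    def test_pair_lattice_mutual_neighbors(self):
        a, b = gen_tract_lattice(1, 2, seed=1)
        assert a.neighbors == {b.tract_id} and b.neighbors == {a.tract_id}

    def test_deterministic_under_seed(self):
        t1 = gen_tract_lattice(2, 2, seed=7)
        t2 = gen_tract_lattice(2, 2, seed=7)
        assert [t.tract_id for t in t1] == [t.tract_id for t in t2]
        assert [t.neighbors for t in t1] == [t.neighbors for t in t2]

    @pytest.mark.parametrize("rows,cols", [(0, 3), (3, 0), (-1, 2), (1, 1)])
    def test_bad_dimensions_rejected(self, rows, cols):
        with pytest.raises(ArgumentError):
            gen_tract_lattice(rows, cols)


class TestDemographics:
    def test_degenerate_weights_concentrate_population(self, lattice_3x3):
        weights = {b: 0.0 for b in AGE_BANDS}
        weights["20-24"] = 1.0
        cells = gen_demographics(lattice_3x3, 100, weights, pct_male=1.0, seed=1)
        outside = cells[(cells["age_band"] != "20-24") | (cells["sex"] != "male")]
        assert (outside["count"] == 0).all()
        assert cells["count"].sum() > 0

    def test_total_population_within_poisson_range(self, lattice_3x3):
        # 4 tracts at mean 250: total ~ Poisson(1000), 3 SE band
        tracts = gen_tract_lattice(2, 2, seed=3)
        cells = gen_demographics(tracts, 250, seed=3)
        total = cells["count"].sum()
        assert abs(total - 1000) <= 3 * np.sqrt(1000)

    def test_deterministic_under_seed(self, lattice_3x3):
        a = gen_demographics(lattice_3x3, 500, seed=9)
        b = gen_demographics(lattice_3x3, 500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_malformed_weights_rejected(self, lattice_3x3):
        bad = dict(DEFAULT_AGE_BAND_WEIGHTS)
        bad["0-4"] += 0.5
        with pytest.raises(ArgumentError):
            gen_demographics(lattice_3x3, 100, bad)
        with pytest.raises(ArgumentError):
            gen_demographics(lattice_3x3, -5)


class TestSurveyPool:
    def test_mean_cholesterol_near_configured(self):
        pool = gen_survey_pool(1000, seed=5)
        cfg = SurveyConfig()
        se = cfg.chol_sd / np.sqrt(len(pool))
        assert abs(pool["total_chol"].mean() - cfg.chol_mean) < 3 * se * 1.2

    def test_single_record_in_plausible_ranges(self):
        rec = gen_survey_pool(1, seed=2).iloc[0]
        assert 20 <= rec["age"] <= 85
        assert rec["sbp"] > 0 and rec["total_chol"] > 0 and rec["hdl"] > 0
        assert rec["sex"] in ("male", "female")

    def test_zero_smoking_prevalence_yields_no_smokers(self):
        pool = gen_survey_pool(500, seed=3, config=SurveyConfig(smoking_prev=0.0))
        assert not pool["smoking"].any()

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ArgumentError):
            gen_survey_pool(0)


class TestClaims:
    def test_zero_prevalence_zero_counts(self, lattice_3x3, small_inputs):
        demo = gen_demographics(lattice_3x3, 300, seed=1)
        claims = gen_claims(lattice_3x3, demo, {"diabetes": 0.0}, seed=1)
        assert (claims["count"] == 0).all()

    def test_unit_prevalence_equals_adult_population(self, lattice_3x3):
        demo = gen_demographics(lattice_3x3, 300, seed=1)
        claims = gen_claims(lattice_3x3, demo, {"diabetes": 1.0}, seed=1)
        adults = (demo[demo["age_band"].isin(ADULT_BANDS)]
                  .groupby("tract_id")["count"].sum())
        for _, row in claims.iterrows():
            assert row["count"] == adults[row["tract_id"]]

    def test_mean_fraction_near_prevalence(self):
        # binomial sampling bound holds in the homogeneous-prevalence mode
        tracts = gen_tract_lattice(8, 8, seed=2)
        demo = gen_demographics(tracts, 500, seed=2)
        claims = gen_claims(tracts, demo, {"diabetes": 0.15}, seed=2,
                            prevalence_logit_sd=0.0)
        adults = (demo[demo["age_band"].isin(ADULT_BANDS)]
                  .groupby("tract_id")["count"].sum())
        frac = claims.set_index("tract_id")["count"] / adults
        se = np.sqrt(0.15 * 0.85 / adults.mean() / len(adults))
        assert abs(frac.mean() - 0.15) < 3 * se * 2
        pd.testing.assert_frame_equal(
            claims, gen_claims(tracts, demo, {"diabetes": 0.15}, seed=2,
                               prevalence_logit_sd=0.0))

    def test_tract_prevalence_heterogeneity(self):
        # with logit jitter on, tract claim fractions spread severalfold
        tracts = gen_tract_lattice(8, 8, seed=3)
        demo = gen_demographics(tracts, 800, seed=3)
        claims = gen_claims(tracts, demo, {"diabetes": 0.15}, seed=3)
        adults = (demo[demo["age_band"].isin(ADULT_BANDS)]
                  .groupby("tract_id")["count"].sum())
        frac = claims.set_index("tract_id")["count"] / adults
        assert frac.max() / max(frac.min(), 1e-9) > 2.0

    def test_bad_prevalence_rejected(self, lattice_3x3, small_inputs):
        demo, _, _ = small_inputs
        with pytest.raises(ArgumentError):
            gen_claims(lattice_3x3, demo, {"diabetes": 1.2})


class TestDeterminants:
    def test_spatial_smoothing_raises_neighbor_similarity(self):
        tracts = gen_tract_lattice(10, 10, seed=1)
        raw = gen_determinants(tracts, spatial_rho=0.0, seed=4)
        smooth = gen_determinants(tracts, spatial_rho=0.8, seed=4)
        from tractrisk import build_weights, morans_i
        w = build_weights(tracts, scheme="rook")
        i_raw = morans_i(raw.set_index("tract_id")["poverty_index"], w)
        i_smooth = morans_i(smooth.set_index("tract_id")["poverty_index"], w)
        assert i_smooth > i_raw + 0.1

    def test_values_respect_support(self, lattice_6x6):
        det = gen_determinants(lattice_6x6, seed=5)
        assert det["hs_grad_pct"].between(40, 100).all()
        assert det["median_income"].ge(15000).all()

    def test_bad_rho_rejected(self, lattice_6x6):
        with pytest.raises(ArgumentError):
            gen_determinants(lattice_6x6, spatial_rho=1.0)


class TestGroundTruth:
    def test_serialization_round_trip(self, tmp_path):
        truth = GroundTruth({"x": -1e-4}, noise_sd=0.002, spatial_rho=0.5, seed=3)
        truth.to_json(tmp_path / "truth.json")
        assert GroundTruth.from_json(tmp_path / "truth.json") == truth

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ArgumentError):
            GroundTruth(noise_sd=-0.1)
        with pytest.raises(ArgumentError):
            GroundTruth(spatial_rho=1.0)


@pytest.fixture(scope="module")
def expected_setup(small_inputs, lattice_6x6):
    demo, _, _ = small_inputs
    pops = demo.groupby("tract_id")["count"].sum()
    rng = np.random.default_rng(0)
    expected = pd.DataFrame({
        "tract_id": pops.index,
        "expected_per_100k": rng.normal(1450, 80, len(pops)),
        "population": pops.to_numpy(),
    })
    det = gen_determinants(lattice_6x6, seed=6)
    return demo, expected, det


class TestObservedDeaths:
    def test_null_truth_reproduces_expected_up_to_rounding(self, expected_setup):
        demo, expected, det = expected_setup
        truth = GroundTruth()
        deaths = gen_observed_deaths(expected, demo, det, truth, seed=1)
        obs = tract_observed_rates(deaths, demo, StandardPopulation.us2000())
        merged = expected.merge(obs, on="tract_id")
        diff = merged["expected_per_100k"] - merged["observed_per_100k"]
        # compensated rounding keeps each tract within ~one death's rate grain
        grain = 100_000.0 / merged["population"]
        assert (diff.abs() <= 2.5 * grain).all()

    def test_real_valued_counts_reproduce_expected_exactly(self, expected_setup):
        demo, expected, det = expected_setup
        deaths = gen_observed_deaths(expected, demo, det, GroundTruth(), seed=1,
                                     integer_counts=False)
        obs = tract_observed_rates(deaths, demo, StandardPopulation.us2000())
        merged = expected.merge(obs, on="tract_id")
        np.testing.assert_allclose(merged["observed_per_100k"],
                                   merged["expected_per_100k"], rtol=1e-9)

    def test_noiseless_ols_recovers_planted_slope(self, expected_setup):
        demo, expected, det = expected_setup
        beta = -2e-4
        truth = GroundTruth({"food_stamps_pct": beta})
        deaths = gen_observed_deaths(expected, demo, det, truth, seed=2)
        obs = tract_observed_rates(deaths, demo, StandardPopulation.us2000())
        merged = expected.merge(obs, on="tract_id").merge(det, on="tract_id")
        y = (merged["expected_per_100k"] - merged["observed_per_100k"]) / 1e5
        slope = np.polyfit(merged["food_stamps_pct"], y, 1)[0]
        assert abs(slope - beta) < 0.1 * abs(beta)

    def test_missing_determinant_tract_named_in_error(self, expected_setup):
        demo, expected, det = expected_setup
        truncated = det.iloc[:-1]
        missing_id = det.iloc[-1]["tract_id"]
        with pytest.raises(DataError, match=str(missing_id)):
            gen_observed_deaths(expected, demo, truncated,
                                GroundTruth({"food_stamps_pct": -1e-4}))

    def test_deterministic_under_seed(self, expected_setup):
        demo, expected, det = expected_setup
        truth = GroundTruth({"food_stamps_pct": -2e-4}, noise_sd=0.002)
        a = gen_observed_deaths(expected, demo, det, truth, seed=3)
        b = gen_observed_deaths(expected, demo, det, truth, seed=3)
        pd.testing.assert_frame_equal(a, b)
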