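# tractrisk

Census-tract analysis of **excess cardiovascular-disease (CVD) death risk**
on a semisynthetic population.

Public-health departments often know *where* people die of CVD (death
certificates by tract) but not *who is at risk* (individual risk factors
are rarely available for a whole county). `tractrisk` closes that gap the
way a county-scale modelling study would:

1. **Build a semisynthetic population** — expand tract demographic
   marginals into individual persons, assign chronic conditions (diabetes,
   hypertension, hyperlipidemia) from insurer claim counts per tract, and
   fill biomarkers and smoking status by hot-deck imputation from a survey
   donor pool matched on sex and 5-year age band.
2. **Assign individual risk** — a proportional-hazards risk equation
   `r₅ = 1 − S₀(sex, age band)^exp(βᵀ(x − c))` gives each adult a 5-year
   CVD death probability (zero for anyone aged ≤ 18), rescaled to the
   4-year observation window by `r₄ = 1 − (1 − r₅)^{4/5}`.
3. **Expected vs observed** — individual 4-year risks are summed per tract
   (*expected* deaths per 100 000); death counts by age band give the
   directly age-standardized *observed* rate (US 2000 standard). The
   headline surface is `difference = expected − observed` per 100 000:
   **negative values mark tracts with excess observed mortality**.
4. **Spatial clustering** — global Moran's *I* of the difference surface
   under row-standardized contiguity weights, with a permutation pseudo
   p-value `(1 + #{I_perm ≥ I_obs}) / (1 + n_perm)`.
5. **Social determinants** — Pearson correlations, Bonferroni-corrected
   univariate OLS of the difference on each tract determinant
   (threshold α/m), multivariate OLS with backward stepwise elimination,
   and a mean-rank composite across determinants.
6. **Counterfactual interventions** — scale beneficial determinants up and
   harmful ones down by 10% or 20%, re-predict each tract's difference by
   the delta method (`Δdiff = Σⱼ βⱼ Δxⱼ`, residuals preserved), and count
   how many tracts (and how much population) remain in excess risk.

Because the county data such a study uses are not publicly depositable, the
package includes a first-class synthetic-data generator
(`tractrisk.synthetic`) that emulates every input — lattice tract
geographies, Table-style age×sex marginals with realistic tract
heterogeneity, survey donors, claim counts, spatially autocorrelated
determinants — and, crucially, **plants a known ground truth**: death
counts are constructed so the tract difference equals
`Σ_d effect_d·(x_d − x̄_d) + ε`, `ε ~ N(0, σ²)`, serialized next to the
data in `truth.json`. Every downstream stage is therefore testable by
parameter recovery.

## Worked example

The all-in-one command simulates a county, builds the population, and runs
the full analysis:

```bash
tractrisk run --rows 8 --cols 8 --mean-pop 2500 --seed 42 --out demo/
```

prints (abbreviated):

```json
{
  "n_tracts": 64,
  "difference_stats": {
    "mean": -56.0, "sd": 462.3,
    "n_negative": 30, "negative_population": 74804,
    "share_negative_population": 0.467
  },
  "calibration": {"slope": 1.059, "intercept": -0.00020},
  "moran": {"I": 0.314, "pseudo_p": 0.001, "z": 3.54},
  "stepwise_terms": ["food_stamps_pct", "no_jobs_pct", "hs_grad_pct",
                     "median_income", "diabetes_pct"],
  "scenarios": {
    "0.1": {"n_negative_tracts": 15, "share_of_total_population": 0.233},
    "0.2": {"n_negative_tracts": 9, "share_of_total_population": 0.140}
  }
}
```

Reading this: 30 of 64 tracts (47% of the population) saw more CVD deaths
than the individual-level model expects. The calibration regression of
observed on expected risk has slope ≈ 1 and intercept ≈ 0, so the risk
equation tracks the mortality surface. Moran's *I* = 0.31 with pseudo
p = 0.001 says excess-risk tracts cluster in space rather than scatter.
Stepwise elimination recovers exactly the five determinants the generator
planted, and a 10% (20%) improvement in those determinants would lift 15
(21) of the 30 excess-risk tracts out of excess.

Artifacts (`demo/`): `tracts.geojson`, `demographics.csv`, `survey.csv`,
`claims.csv`, `determinants.csv`, `truth.json`, `population.csv`,
`expected.csv`, `deaths.csv`, `summary.csv`, `univariate.csv` — headered
CSV with a provenance comment line, GeoJSON for geometry.

Each stage is also a separate subcommand (`simulate`, `build`, `risk`,
`excess`, `spatial`, `regress`, `intervene`) over the same files, and the
whole pipeline is importable (`tractrisk.pipeline.run_pipeline`,
`tractrisk.risk.risk_5yr`, `tractrisk.spatial.morans_permutation`, ...).
`tractrisk regress --model income|income_education|biological|combined`
fits the named multivariate models (the biological variables are the
tract disease prevalences derived from claims); `--model custom --terms
a,b,c` fits any column set.

The packaged default risk model
(`src/tractrisk/data/default_risk_model.json`) is **synthetic** — a
Gompertz baseline hazard with plausible log-hazard-ratios for smoking,
diabetes, systolic blood pressure and total cholesterol — not the
published coefficients of any specific risk equation. Pass `--model
your_model.json` for substantive work.

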