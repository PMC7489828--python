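# Methods

This note documents the models, numerical choices and limitations behind
`tractrisk`. It describes what the code computes; every number quoted here
is produced by the test suite or `scripts/acceptance.py`, not asserted.

## The excess-risk construction

The analysis grain is the census tract. Two per-tract quantities are
contrasted, both as 4-year CVD death risks per 100 000 persons:

- **Expected**: each simulated person receives a 5-year death probability
  from the risk equation (below), rescaled to 4 years, and these are
  summed over the tract; the denominator is the full tract population,
  children included.
- **Observed**: death counts by 5-year age band are directly
  age-standardized, `rate = 10⁵ · Σ_b w_b · deaths_b / pop_b`, and the
  observed death total is `rate × population / 10⁵`.

`difference = expected − observed` per 100 000. Negative differences mean
the tract experienced more deaths than its individual-level risk profile
explains — candidate targets for intervention. Tracts below a configurable
minimum population (default 50) are excluded and reported, because
standardized rates on tiny denominators are unstable.

**Standard population.** Direct standardization defaults to the US 2000
standard-million weights over the 18 bands 0–4 … 85+; any weight vector
summing to 1 can be supplied. A band with zero population and zero deaths
contributes nothing at its full weight (weights are not renormalized);
deaths in a zero-population band are a data error.

## Risk equation

Proportional-hazards survival form:

    r5 = 1 − S0(sex, band) ^ exp( Σ_j β_j (x_j − c_j) )

with covariates smoking, diabetes, systolic blood pressure (centered at
120 mm Hg) and total cholesterol (centered at 190 mg/dL). Anyone aged 18
or younger receives exactly zero risk. The default model's baseline is a
Gompertz hazard `h₀(a) = 0.001368·e^{0.095(a−60)}` per year (×1.45 for
males), converted to 5-year band survivals `S0 = e^{−5h₀}`; the scale was
set once so the default simulated county's mean expected rate lands near
1 440 per 100 000 over 4 years, a realistic county-level CVD mortality
level. The default file is clearly labeled synthetic; it is *not* a
published equation's coefficients, and users doing substantive work must
supply their own.

**Horizon rescaling.** 5→4-year scaling assumes a constant hazard within
the horizon: `r4 = 1 − (1 − r5)^{4/5}`. A linear mode (`0.8·r5`) exists
behind a flag; the two differ by < 0.1% at typical risks. The hazard form
is the default because it is probabilistically coherent at any risk level.

## Population construction

- `expand_cells` turns (tract, band, sex, count) marginals into persons;
  ages are uniform within the band, with 85+ treated as uniform on
  [85, 100). Person counts are conserved exactly at every stage.
- `assign_conditions`: a fraction (default 0.8) of each tract's adults is
  marked claims-covered; for each condition exactly
  `min(claim count, covered size)` covered adults are flagged (clipped
  with a warning when claims exceed the covered pool). "Adult" is age
  > 18, matching the risk cutoff.
- `impute_from_donors`: hot-deck matching on (sex, 5-year band), widening
  to (sex, adjacent band) and then sex-only when a stratum has no donor;
  donors are drawn uniformly with replacement. SBP, total and HDL
  cholesterol and smoking always come from the donor; condition flags come
  from the donor only for persons *not* covered by claims — claimed
  conditions are never overwritten (claims are treated as the more
  reliable source). Children are matched through the same ladder (ending
  at sex-only); their biomarkers are carried but never used, since their
  risk is zero.

## Synthetic-data generator

The generator is the package's substitute for non-depositable county data;
its defaults are chosen once to emulate a realistic mid-size US county and
are not tuned per analysis.

- **Geography**: an R×C lattice of unit squares with rook adjacency
  (default analysis scale 19×18 = 342 tracts).
- **Demographics**: tract totals Poisson(mean 3 400); band×sex splits are
  multinomial. Tracts are deliberately heterogeneous: each tract tilts the
  age-band weights exponentially (`w_b ∝ w_b·e^{g(mid_b−42)/25}`,
  `g ~ N(0, 0.30)`) and jitters the male share on the logit scale
  (SD 0.25). This reproduces the wide tract-to-tract spread real counties
  show (simulated tract mean ages ≈ 27–55, SD ≈ 6; % male SD ≈ 5) and
  gives the expected-risk surface genuine variance, without which the
  observed-vs-expected calibration regression is unidentifiable.
- **Survey pool**: ages uniform 20–85; SBP/cholesterol normal around
  age-trended means centered so the configured value is the marginal mean
  (defaults: SBP 122, total cholesterol 189, HDL 52); chronic-condition
  prevalences scale multiplicatively with age (so a configured 0 stays 0);
  smoking skews younger.
- **Claims**: per tract, Binomial(adults 20+, p_t) with p_t jittered
  around the configured prevalence on the logit scale (SD 0.6), giving the
  severalfold tract variation in disease burden real claims data show.
  Degenerate prevalences 0 and 1 are preserved exactly.
- **Determinants**: ten tract variables (income, education, food stamps,
  joblessness, insurance, poverty index, obesity, vehicle access, vacant
  housing) with stated means/SDs, clipped to their supports. Spatial
  autocorrelation mixes each tract's i.i.d. draw with its neighbors' mean
  at weight ρ (default 0.6), then re-standardizes — enough structure for
  Moran's I to detect without a full spatial-process model.
- **Deaths with planted truth**: the target observed rate per tract is
  `expected − 10⁵·[Σ_d effect_d(x_d − x̄_d) + ε]`, ε ~ N(0, noise_sd),
  floored at 0. Effects and noise are on the risk-fraction scale
  (default effects ≈ 10⁻⁴ per determinant unit, noise SD 0.003 ≈ 300 per
  100 000 — magnitudes typical of tract-level regressions). Determinants
  are mean-centered in the planting so the difference surface stays near
  zero and rates stay positive; centering changes no recoverable slope.
  Deaths are spread across bands at a uniform rate, so direct
  standardization recovers the target exactly before integerization.

**Integer death counts.** Counts are integerized by *compensated*
rounding: band counts are floored, then incremented greedily (largest
fractional part first) whenever that shrinks the tract's standardized-rate
error under the analysis' standard weights. This keeps the realized rate
within about half a death of the target (residual grain ≈ 10–20 per
100 000 at tract population 2 000) and — unlike independent per-band
rounding, whose error is a sawtooth in the target rate — leaves no
systematic structure that would bias the calibration regression. Binomial
realization and exact real-valued counts are available behind flags.

**What the generator does not emulate**: household/school/workplace
structure, survey design weights, race/ethnicity, migration, correlation
between determinants and demographic composition, and non-linear or
spatially varying determinant effects. Passing recovery tests therefore
shows the *estimators* are correct under the stated data-generating
process, not that the process captures every feature of real county data.

## Spatial statistics

Row-standardized contiguity weights; rook (shared edge) from adjacency
lists, queen (any shared point) derived from geometry, queen preferred
when geometry is available. Islands keep zero rows, are flagged, and are
excluded from the statistic. Moran's I uses the standard cross-product
form and matches a brute-force O(n²) double sum to 1e-12 in tests.

The permutation test reassigns values across tracts (mean and total sum of
squares are permutation-invariant, so only the cross-product is
recomputed; permutations are evaluated vectorized in blocks).
`pseudo_p = (1 + #more-extreme) / (1 + n_permutations)`; with 999
permutations the attainable floor is 0.001. The default alternative is
**"greater"** — a fixed-side test for positive clustering, which is the
scientific question for a risk surface and holds the null rejection rate
at the nominal level (measured 3–7% at p ≤ 0.05 over 500 null replicates).
The folded "toward the observed deviation" convention some GIS tools print
is available as `alternative="directed"`; note its null rejection rate at
a nominal cutoff is roughly double, which is why it is not the default.
The z-score standardizes the observed I by the permutation distribution
(SD with ddof = 1).

## Determinant regressions

All regressions put the difference on the risk-fraction scale
(per-100k/10⁵), the scale on which tract-level slopes and residual SEs are
conventionally reported. Univariate screening applies a Bonferroni
threshold α/m with m the number of determinants actually screened
(all-missing columns are skipped with a warning; fits are complete-case).
Besides the social determinants, the pipeline derives "biological" tract
variables from the claims table — percent of adults (20+) with diabetes,
hypertension and hyperlipidemia — and exposes four named multivariate
presets (`income`, `income_education`, `biological`, `combined`) alongside
arbitrary custom term lists.
Backward stepwise elimination drops the highest-p term above
p_remove = 0.05, refits, and stops when all retained terms are significant
or one term remains; exact p ties break toward the later candidate — a
documented, deterministic rule. The full per-step trace (terms, adjusted
R², dropped term) is returned so the selection is auditable. The mean-rank
composite ranks tracts 1 (most favorable) to n per determinant honoring
each determinant's orientation, averages ranks (ties averaged), and
regresses the difference on the mean rank; it is invariant to monotone
transforms of any determinant.

## Interventions

"Improve by 10%/20%" is read as a *relative* (multiplicative) change —
the only reading that applies uniformly to percentages and dollar incomes;
a percentage-point mode exists behind a flag. Percentage columns are
clamped to [0, 100]; the high-school special rule (baseline ≥ 90% → 100%)
is applied after scaling, keyed on the baseline value. Prediction is
delta-method on a fitted model: each tract keeps its unexplained residual
and shifts by `Σ_j β_j Δx_j`; an identity scenario reproduces the baseline
exactly, and any scenario whose term-wise shifts are all beneficial can
only shrink the negative-tract count. "Excess" is strictly
`difference < 0`.

## Numerical and testing choices

- Every OLS fit is checked against a hand-coded normal-equations +
  t-inference oracle to 1e-10; Moran's I against the dense double sum to
  1e-12.
- Conservation (Σ tract expected deaths = Σ person risks) holds to 1e-9.
- All generators and the pipeline are pure functions of (parameters,
  seed); fixed configs reproduce artifacts byte for byte.
- Statistical guarantees are tested at fixed, pre-chosen seeds:
  permutation type-I calibration uses 500 replicates at 36 tracts;
  planted-slope CI coverage uses 200 replicates on a 10×10 lattice with
  the person-level stage generated once (the replicated stages —
  determinants, noise, death realization — are the ones recovery actually
  exercises); calibration self-consistency uses 20 replicates at 64 tracts
  and asserts ≥ 90% CI coverage, since a 95% interval cannot cover in
  every replicate by construction.
- One knife-edge check is expected to sit at its nominal boundary: under
  p_remove = 0.05 the probability that stepwise elimination drops a
  pure-noise predictor is exactly the nominal 95%, so a 200-replicate run
  hovers at that threshold (the frozen seeds realize 94%, consistent with
  correct behavior; the noise-term p-values are verified uniform).

## Limitations

Associations between determinants and excess risk are correlational; the
delta-method counterfactuals inherit every causal caveat of the fitted
regression. The semisynthetic construction bounds realism: conditions
enter risk only through the risk equation's covariates, determinants do
not feed back into demographics, and local (tract-level) cluster
statistics are not implemented — the clustering test is global only.
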