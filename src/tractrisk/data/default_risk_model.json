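{
 "description": "Synthetic default CVD-death risk model: Gompertz baseline hazard 0.001368*exp(0.095*(age-60)) (x1.45 for males) converted to 5-year baseline survival per sex and age band. Coefficients are plausible log-hazard-ratios, NOT the published values of any risk equation; supply your own model for substantive work.",
 "baseline_survival": {
  "male": {
   "0-4": 0.999958,
   "5-9": 0.999932,
   "10-14": 0.999891,
   "15-19": 0.999825,
   "20-24": 0.999719,
   "25-29": 0.999548,
   "30-34": 0.999273,
   "35-39": 0.998831,
   "40-44": 0.998121,
   "45-49": 0.99698,
   "50-54": 0.995148,
   "55-59": 0.992209,
   "60-64": 0.987502,
   "65-69": 0.97998,
   "70-74": 0.968003,
   "75-79": 0.949051,
   "80-84": 0.919351,
   "85+": 0.804588
  },
  "female": {
   "0-4": 0.999971,
   "5-9": 0.999953,
   "10-14": 0.999925,
   "15-19": 0.999879,
   "20-24": 0.999806,
   "25-29": 0.999688,
   "30-34": 0.999498,
   "35-39": 0.999194,
   "40-44": 0.998704,
   "45-49": 0.997916,
   "50-54": 0.996651,
   "55-59": 0.994621,
   "60-64": 0.991364,
   "65-69": 0.986149,
   "70-74": 0.977822,
   "75-79": 0.964579,
   "80-84": 0.943658,
   "85+": 0.860753
  }
 },
 "coefficients": {
  "smoking": 0.6,
  "diabetes": 0.65,
  "sbp": 0.016,
  "total_chol": 0.003
 },
 "centers": {
  "smoking": 0.0,
  "diabetes": 0.0,
  "sbp": 120.0,
  "total_chol": 190.0
 },
 "horizon_years": 5.0
}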