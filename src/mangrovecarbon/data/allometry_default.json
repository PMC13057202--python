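[
 {
  "species_id": "R_stylosa",
  "component": "above_ground",
  "predictor": "dbh",
  "a": 0.082235,
  "b": 2.2,
  "carbon_factor": 0.45,
  "form": "power"
 },
 {
  "species_id": "R_stylosa",
  "component": "below_ground",
  "predictor": "dbh",
  "a": 0.056847,
  "b": 2.0,
  "carbon_factor": 0.39,
  "form": "power"
 },
 {
  "species_id": "B_gymnorrhiza",
  "component": "above_ground",
  "predictor": "dbh",
  "a": 0.05734,
  "b": 2.2,
  "carbon_factor": 0.45,
  "form": "power"
 },
 {
  "species_id": "B_gymnorrhiza",
  "component": "below_ground",
  "predictor": "dbh",
  "a": 0.040048,
  "b": 2.0,
  "carbon_factor": 0.39,
  "form": "power"
 },
 {
  "species_id": "A_marina",
  "component": "above_ground",
  "predictor": "dbh",
  "a": 0.093249,
  "b": 2.2,
  "carbon_factor": 0.45,
  "form": "power"
 },
 {
  "species_id": "A_marina",
  "component": "below_ground",
  "predictor": "dbh",
  "a": 0.112527,
  "b": 2.0,
  "carbon_factor": 0.39,
  "form": "power"
 },
 {
  "species_id": "A_corniculatum",
  "component": "above_ground",
  "predictor": "basal_diameter",
  "a": 0.057235,
  "b": 2.2,
  "carbon_factor": 0.45,
  "form": "power"
 },
 {
  "species_id": "A_corniculatum",
  "component": "below_ground",
  "predictor": "basal_diameter",
  "a": 0.03352,
  "b": 2.0,
  "carbon_factor": 0.39,
  "form": "power"
 }
]
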