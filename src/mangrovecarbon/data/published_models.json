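[
 {
  "response": "AGC",
  "group": ["R_stylosa", "A_marina"],
  "predictors": ["H_Mean"],
  "coefficients": [-28.49, 33.50]
 },
 {
  "response": "BGC",
  "group": ["R_stylosa", "A_marina"],
  "predictors": ["H_Mean"],
  "coefficients": [2.75, 9.20]
 },
 {
  "response": "AGC",
  "group": ["A_corniculatum"],
  "predictors": ["RE_Mean"],
  "coefficients": [-464.53, 20.07]
 },
 {
  "response": "BGC",
  "group": ["A_corniculatum"],
  "predictors": ["RE_Mean"],
  "coefficients": [-187.21, 8.09]
 },
 {
  "response": "AGC",
  "group": ["B_gymnorrhiza"],
  "predictors": ["B_Var", "R_Con"],
  "coefficients": [17.14, 293.07, -31.21]
 },
 {
  "response": "BGC",
  "group": ["B_gymnorrhiza"],
  "predictors": ["B_Var", "NIR_Hom", "B_Con"],
  "coefficients": [-54.10, 95.55, 241.071, -20.18]
 }
]
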