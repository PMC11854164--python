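{
 "note": "Reference values for the 17-run designed experiment. source='reported' values are printed in the reference study; source='derived' values are recomputed from its printed data by ordinary least squares and disagree with misprinted entries.",
 "coefficients_reported": {
  "source": "reported",
  "values": {"Intercept": 27.522, "A": 4.575, "B": 1.95, "C": 1.665,
             "AB": 0.730, "AC": 1.660, "BC": -0.170,
             "A2": -7.681, "B2": -3.511, "C2": -3.341},
  "comment": "The signs of AB and AC and the digits of B2 as reported do not reproduce the reported predicted column; the derived values do."
 },
 "coefficients_derived": {
  "source": "derived",
  "values": {"Intercept": 27.522, "A": 4.575, "B": 1.95, "C": 1.665,
             "AB": -0.730, "AC": -1.660, "BC": -0.170,
             "A2": -7.681, "B2": -3.551, "C2": -3.341}
 },
 "predicted_yield": {
  "source": "reported",
  "values": [9.035, 19.645, 14.395, 22.085, 8.6, 21.07, 15.25, 21.08,
             16.845, 21.085, 20.515, 24.075,
             27.522, 27.522, 27.522, 27.522, 27.522]
 },
 "anova": {
  "source": "reported",
  "rows": {
   "Model":       {"ss": 614.36, "df": 9, "ms": 68.26, "f": 3.84, "p": 0.0451},
   "A":           {"ss": 167.45, "df": 1, "f": 9.41, "p": 0.0181},
   "B":           {"ss": 30.42,  "df": 1, "f": 1.71, "p": 0.2324},
   "C":           {"ss": 22.18,  "df": 1, "f": 1.25, "p": 0.3011},
   "AB":          {"ss": 2.13,   "df": 1, "f": 0.1198, "p": 0.7395},
   "AC":          {"ss": 11.02,  "df": 1, "f": 0.6193, "p": 0.4571},
   "BC":          {"ss": 0.1156, "df": 1, "f": 0.0065, "p": 0.938},
   "A2":          {"ss": 248.41, "df": 1, "f": 13.96, "p": 0.0073},
   "B2":          {"ss": 53.09,  "df": 1, "f": 2.98, "p": 0.1278},
   "C2":          {"ss": 47.0,   "df": 1, "f": 2.64, "p": 0.1482},
   "Residual":    {"ss": 124.59, "df": 7, "ms": 17.8},
   "Lack of Fit": {"ss": 86.51,  "df": 3, "ms": 28.84, "f": 3.03, "p": 0.1561},
   "Pure Error":  {"ss": 38.08,  "df": 4, "ms": 9.52},
   "Cor Total":   {"ss": 738.95, "df": 16}
  }
 },
 "r2_reported": {"source": "reported", "value": 0.8358,
  "comment": "Not equal to the SS ratio of the reported ANOVA (614.36/738.95 = 0.8314); likely computed on the unpublished 33-run set."},
 "r2_derived": {"source": "derived", "value": 0.8314},
 "optima": {
  "source": "reported",
  "rsm":   {"pH": 5.997, "enzyme_pct": 3.825, "time_min": 79.895, "predicted": 27.95, "actual": 28.54},
  "bp":    {"pH": 5.287, "enzyme_pct": 3.801, "time_min": 59.269, "predicted": 27.71, "actual": 28.12},
  "ga_bp": {"pH": 5.248, "enzyme_pct": 3.0,   "time_min": 70.153, "predicted": 28.42, "actual": 28.35},
  "comment": "The reported surface optimum is not the maximizer of the surface fitted to the printed runs (derived stationary point approx. coded (0.267, 0.243, 0.177), predicted 28.52); recorded, not emulated."
 },
 "comparison_metrics": {
  "source": "reported",
  "r2":   {"rsm": 0.8358, "bp": 0.8668, "ga_bp": 0.9065},
  "rmse": {"rsm": 2.8678, "bp": 2.0423, "ga_bp": 1.6215},
  "aad":  {"rsm": 2.26,   "bp": 1.99,   "ga_bp": 1.12},
  "comment": "Computed by the reference study on a 33-run set it does not print; not reproducible from the packaged 17 runs."
 },
 "validation_squared_error": {
  "source": "reported",
  "values": {"rsm": 0.3410, "bp": 0.1616, "ga_bp": 0.0049},
  "comment": "ga_bp row is exactly (28.42-28.35)^2; the rsm row as reported (0.3410) differs from (27.95-28.54)^2 = 0.3481."
 },
 "alternate_printed_levels": {
  "source": "reported",
  "comment": "The factor-level table as separately printed (enzyme 2/3/4 %, time 20/40/60 min) contradicts the run table's actual settings; the fixture uses the run table's levels, to which the yields and predictions belong.",
  "values": {"pH": [4, 5, 6], "enzyme_pct": [2, 3, 4], "time_min": [20, 40, 60]}
 }
}
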