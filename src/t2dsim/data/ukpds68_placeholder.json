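{
  "name": "ukpds68-placeholder",
  "style": "ukpds68",
  "_comment": "Synthetic placeholder coefficients in the classic (UKPDS-68-style) equation-set layout: first events only, no expanded risk factors. Values are NOT the published UKPDS 68 estimates; see the companion ukpds82 placeholder registry.",
  "equations": [
    {
      "endpoint": "mi",
      "kind": "event",
      "form": "weibull",
      "shape": 1.3,
      "intercept": -5.7,
      "eligibility": "mi_count == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.06, "transform": "offset", "parameter": 60.0},
        {"name": "hba1c", "coefficient": 0.14, "transform": "offset", "parameter": 7.5},
        {"name": "sbp", "coefficient": 0.009, "transform": "offset", "parameter": 140.0},
        {"name": "tchdl", "coefficient": 0.12, "transform": "offset", "parameter": 4.0},
        {"name": "smoker", "coefficient": 0.35, "transform": "indicator", "parameter": 0.0},
        {"name": "female", "coefficient": -0.35, "transform": "indicator", "parameter": 0.0}
      ]
    },
    {
      "endpoint": "stroke",
      "kind": "event",
      "form": "weibull",
      "shape": 1.4,
      "intercept": -6.7,
      "eligibility": "stroke_count == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.075, "transform": "offset", "parameter": 60.0},
        {"name": "sbp", "coefficient": 0.012, "transform": "offset", "parameter": 140.0},
        {"name": "af", "coefficient": 0.6, "transform": "indicator", "parameter": 0.0},
        {"name": "smoker", "coefficient": 0.25, "transform": "indicator", "parameter": 0.0}
      ]
    },
    {
      "endpoint": "chf",
      "kind": "event",
      "form": "weibull",
      "shape": 1.5,
      "intercept": -7.1,
      "eligibility": "chf == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.08, "transform": "offset", "parameter": 60.0},
        {"name": "weight", "coefficient": 0.012, "transform": "offset", "parameter": 85.0},
        {"name": "sbp", "coefficient": 0.006, "transform": "offset", "parameter": 140.0}
      ]
    },
    {
      "endpoint": "ihd",
      "kind": "event",
      "form": "weibull",
      "shape": 1.2,
      "intercept": -5.95,
      "eligibility": "ihd == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.05, "transform": "offset", "parameter": 60.0},
        {"name": "tchdl", "coefficient": 0.15, "transform": "offset", "parameter": 4.0},
        {"name": "female", "coefficient": -0.25, "transform": "indicator", "parameter": 0.0}
      ]
    },
    {
      "endpoint": "amputation",
      "kind": "event",
      "form": "exponential",
      "intercept": -5.3,
      "eligibility": "amputation == 0",
      "covariates": [
        {"name": "hba1c", "coefficient": 0.16, "transform": "offset", "parameter": 7.5},
        {"name": "pvd", "coefficient": 0.9, "transform": "indicator", "parameter": 0.0},
        {"name": "smoker", "coefficient": 0.3, "transform": "indicator", "parameter": 0.0}
      ]
    },
    {
      "endpoint": "blindness",
      "kind": "event",
      "form": "exponential",
      "intercept": -5.25,
      "eligibility": "blindness == 0",
      "covariates": [
        {"name": "hba1c", "coefficient": 0.17, "transform": "offset", "parameter": 7.5},
        {"name": "sbp", "coefficient": 0.006, "transform": "offset", "parameter": 140.0}
      ]
    },
    {
      "endpoint": "esrd",
      "kind": "event",
      "form": "exponential",
      "intercept": -6.0,
      "eligibility": "esrd == 0",
      "covariates": [
        {"name": "sbp", "coefficient": 0.010, "transform": "offset", "parameter": 140.0},
        {"name": "hba1c", "coefficient": 0.10, "transform": "offset", "parameter": 7.5}
      ]
    },
    {
      "endpoint": "death_nohist",
      "kind": "mortality",
      "form": "gompertz",
      "shape": 0.09,
      "intercept": -6.4,
      "eligibility": "mi_count == 0 and stroke_count == 0 and chf == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.07, "transform": "offset", "parameter": 60.0},
        {"name": "female", "coefficient": -0.2, "transform": "indicator", "parameter": 0.0},
        {"name": "smoker", "coefficient": 0.4, "transform": "indicator", "parameter": 0.0},
        {"name": "hba1c", "coefficient": 0.08, "transform": "offset", "parameter": 7.5}
      ]
    },
    {
      "endpoint": "death_hist",
      "kind": "mortality",
      "form": "gompertz",
      "shape": 0.09,
      "intercept": -4.85,
      "eligibility": "mi_count >= 1 or stroke_count >= 1 or chf >= 1",
      "covariates": [
        {"name": "age", "coefficient": 0.07, "transform": "offset", "parameter": 60.0}
      ]
    }
  ]
}
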