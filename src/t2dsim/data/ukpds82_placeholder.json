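{
  "name": "ukpds82-placeholder",
  "style": "ukpds82",
  "_comment": "Synthetic placeholder coefficients in the expanded (UKPDS-82-style) equation-set layout: secondary MI/stroke equations, granular mortality, and the expanded risk factors (WBC, LDL, eGFR, heart rate, haemoglobin, albuminuria). Values are NOT the published UKPDS 82 estimates; they are chosen to give realistic annualized T2DM complication rates (~0.2-2.5 events per 100 person-years). Transcribe published coefficients into this schema to run the real equation set.",
  "equations": [
    {
      "endpoint": "mi",
      "kind": "event",
      "form": "weibull",
      "shape": 1.3,
      "intercept": -5.8,
      "eligibility": "mi_count == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.06, "transform": "offset", "parameter": 60.0},
        {"name": "hba1c", "coefficient": 0.13, "transform": "offset", "parameter": 7.5},
        {"name": "sbp", "coefficient": 0.008, "transform": "offset", "parameter": 140.0},
        {"name": "ldl", "coefficient": 0.28, "transform": "offset", "parameter": 3.0},
        {"name": "smoker", "coefficient": 0.35, "transform": "indicator", "parameter": 0.0},
        {"name": "female", "coefficient": -0.35, "transform": "indicator", "parameter": 0.0},
        {"name": "egfr", "coefficient": -0.006, "transform": "offset", "parameter": 77.7},
        {"name": "wbc", "coefficient": 0.05, "transform": "offset", "parameter": 6.9}
      ]
    },
    {
      "endpoint": "secondary_mi",
      "kind": "event",
      "form": "exponential",
      "intercept": -3.9,
      "eligibility": "mi_count >= 1",
      "covariates": [
        {"name": "age", "coefficient": 0.05, "transform": "offset", "parameter": 60.0},
        {"name": "hba1c", "coefficient": 0.10, "transform": "offset", "parameter": 7.5}
      ]
    },
    {
      "endpoint": "stroke",
      "kind": "event",
      "form": "weibull",
      "shape": 1.4,
      "intercept": -6.6,
      "eligibility": "stroke_count == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.07, "transform": "offset", "parameter": 60.0},
        {"name": "sbp", "coefficient": 0.012, "transform": "offset", "parameter": 140.0},
        {"name": "af", "coefficient": 0.6, "transform": "indicator", "parameter": 0.0},
        {"name": "smoker", "coefficient": 0.25, "transform": "indicator", "parameter": 0.0}
      ]
    },
    {
      "endpoint": "secondary_stroke",
      "kind": "event",
      "form": "exponential",
      "intercept": -4.1,
      "eligibility": "stroke_count >= 1",
      "covariates": [
        {"name": "age", "coefficient": 0.05, "transform": "offset", "parameter": 60.0},
        {"name": "sbp", "coefficient": 0.010, "transform": "offset", "parameter": 140.0}
      ]
    },
    {
      "endpoint": "chf",
      "kind": "event",
      "form": "weibull",
      "shape": 1.5,
      "intercept": -7.0,
      "eligibility": "chf == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.08, "transform": "offset", "parameter": 60.0},
        {"name": "weight", "coefficient": 0.01, "transform": "offset", "parameter": 85.0},
        {"name": "heart_rate", "coefficient": 0.012, "transform": "offset", "parameter": 72.0},
        {"name": "egfr", "coefficient": -0.008, "transform": "offset", "parameter": 77.7}
      ]
    },
    {
      "endpoint": "ihd",
      "kind": "event",
      "form": "weibull",
      "shape": 1.2,
      "intercept": -5.9,
      "eligibility": "ihd == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.05, "transform": "offset", "parameter": 60.0},
        {"name": "ldl", "coefficient": 0.30, "transform": "offset", "parameter": 3.0},
        {"name": "female", "coefficient": -0.25, "transform": "indicator", "parameter": 0.0}
      ]
    },
    {
      "endpoint": "amputation",
      "kind": "event",
      "form": "exponential",
      "intercept": -5.2,
      "eligibility": "amputation == 0",
      "covariates": [
        {"name": "hba1c", "coefficient": 0.15, "transform": "offset", "parameter": 7.5},
        {"name": "pvd", "coefficient": 0.9, "transform": "indicator", "parameter": 0.0},
        {"name": "smoker", "coefficient": 0.3, "transform": "indicator", "parameter": 0.0}
      ]
    },
    {
      "endpoint": "ulcer",
      "kind": "event",
      "form": "exponential",
      "intercept": -5.0,
      "eligibility": "ulcer == 0",
      "covariates": [
        {"name": "hba1c", "coefficient": 0.12, "transform": "offset", "parameter": 7.5},
        {"name": "pvd", "coefficient": 0.5, "transform": "indicator", "parameter": 0.0}
      ]
    },
    {
      "endpoint": "blindness",
      "kind": "event",
      "form": "exponential",
      "intercept": -5.3,
      "eligibility": "blindness == 0",
      "covariates": [
        {"name": "hba1c", "coefficient": 0.18, "transform": "offset", "parameter": 7.5},
        {"name": "sbp", "coefficient": 0.006, "transform": "offset", "parameter": 140.0}
      ]
    },
    {
      "endpoint": "esrd",
      "kind": "event",
      "form": "weibull",
      "shape": 1.6,
      "intercept": -7.9,
      "eligibility": "esrd == 0",
      "covariates": [
        {"name": "egfr", "coefficient": -0.025, "transform": "offset", "parameter": 77.7},
        {"name": "albuminuria", "coefficient": 0.8, "transform": "indicator", "parameter": 0.0},
        {"name": "sbp", "coefficient": 0.008, "transform": "offset", "parameter": 140.0}
      ]
    },
    {
      "endpoint": "death_nohist",
      "kind": "mortality",
      "form": "gompertz",
      "shape": 0.09,
      "intercept": -6.5,
      "eligibility": "mi_count == 0 and stroke_count == 0 and chf == 0",
      "covariates": [
        {"name": "age", "coefficient": 0.07, "transform": "offset", "parameter": 60.0},
        {"name": "female", "coefficient": -0.2, "transform": "indicator", "parameter": 0.0},
        {"name": "smoker", "coefficient": 0.4, "transform": "indicator", "parameter": 0.0},
        {"name": "haemoglobin", "coefficient": -0.02, "transform": "offset", "parameter": 145.0},
        {"name": "hba1c", "coefficient": 0.08, "transform": "offset", "parameter": 7.5}
      ]
    },
    {
      "endpoint": "death_hist",
      "kind": "mortality",
      "form": "gompertz",
      "shape": 0.09,
      "intercept": -4.9,
      "eligibility": "mi_count >= 1 or stroke_count >= 1 or chf >= 1",
      "covariates": [
        {"name": "age", "coefficient": 0.07, "transform": "offset", "parameter": 60.0},
        {"name": "haemoglobin", "coefficient": -0.02, "transform": "offset", "parameter": 145.0}
      ]
    },
    {
      "endpoint": "death_esrd",
      "kind": "mortality",
      "form": "exponential",
      "intercept": -2.6,
      "eligibility": "esrd >= 1",
      "covariates": [
        {"name": "age", "coefficient": 0.04, "transform": "offset", "parameter": 60.0}
      ]
    }
  ]
}
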