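{
  "name": "a30p-courtship-screen",
  "rules": [
    {
      "predicted": "healthy",
      "probability": null,
      "support": null,
      "conditions": [
        {"feature": "nse_count", "kind": "interval", "low": 3, "high": 5, "note": "reported within-interval average 4.40"}
      ]
    },
    {
      "predicted": "healthy",
      "probability": null,
      "support": null,
      "conditions": [
        {"feature": "orientation_time_s", "kind": "interval", "low": 294.0, "high": 349.51, "note": "reported within-interval average 320.84"},
        {"feature": "total_time_s", "kind": "interval", "low": 354.95, "high": 407.0, "note": "reported within-interval average 376.29"}
      ]
    },
    {
      "predicted": "healthy",
      "probability": null,
      "support": null,
      "conditions": [
        {"feature": "atc_count", "kind": "exact_count", "low": 3, "high": 3}
      ]
    },
    {
      "predicted": "healthy",
      "probability": null,
      "support": null,
      "conditions": [
        {"feature": "licking_count", "kind": "interval", "low": 21, "high": 56, "note": "reported within-interval average 34.50"},
        {"feature": "nse_count", "kind": "interval", "low": 6, "high": 17, "note": "reported within-interval average 4.40 (inconsistent with the interval; kept verbatim)"}
      ]
    },
    {
      "predicted": "healthy",
      "probability": null,
      "support": null,
      "conditions": [
        {"feature": "nse_count", "kind": "interval", "low": 1, "high": 2, "note": "reported within-interval average 100.40 (inconsistent with the interval; kept verbatim)"}
      ]
    },
    {
      "predicted": "healthy",
      "probability": null,
      "support": null,
      "conditions": [
        {"feature": "vibration_time_s", "kind": "interval", "low": 0.0, "high": 77.0, "note": "reported within-interval average 15.72"},
        {"feature": "nse_count", "kind": "interval", "low": 35, "high": 51, "note": "reported within-interval average 43.43"}
      ]
    },
    {
      "predicted": "healthy",
      "probability": null,
      "support": null,
      "conditions": [
        {"feature": "total_time_s", "kind": "interval", "low": 516.58, "high": 519.91, "note": "reported within-interval average 517.94"}
      ]
    }
  ]
}
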