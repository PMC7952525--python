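{
  "name": "model5",
  "components": [
    {
      "variable": "transductal_diameter",
      "kind": "numeric-binned",
      "bins": [
        {"low": 0.0, "high": 0.0, "low_closed": true, "high_closed": true, "score": 0},
        {"low": 0.0, "high": 1.5, "low_closed": false, "high_closed": false, "score": 1},
        {"low": 1.5, "high": 3.0, "low_closed": true, "high_closed": true, "score": 2},
        {"low": 3.0, "high": null, "low_closed": false, "high_closed": false, "score": 3}
      ]
    },
    {
      "variable": "ductal_vmax_vmin_ratio",
      "kind": "numeric-binned",
      "bins": [
        {"low": 0.0, "high": 0.0, "low_closed": true, "high_closed": true, "score": 0},
        {"low": 0.0, "high": 1.5, "low_closed": false, "high_closed": false, "score": 1},
        {"low": 1.5, "high": 2.0, "low_closed": true, "high_closed": true, "score": 2},
        {"low": 2.0, "high": null, "low_closed": false, "high_closed": false, "score": 3}
      ]
    },
    {
      "variable": "lpa_diastolic_velocity",
      "kind": "numeric-binned",
      "bins": [
        {"low": 0.0, "high": 0.0, "low_closed": true, "high_closed": true, "score": 0},
        {"low": 0.0, "high": 30.0, "low_closed": false, "high_closed": false, "score": 1},
        {"low": 30.0, "high": 50.0, "low_closed": true, "high_closed": true, "score": 2},
        {"low": 50.0, "high": null, "low_closed": false, "high_closed": false, "score": 3}
      ]
    },
    {
      "variable": "dao_flow_direction",
      "kind": "categorical",
      "categories": {"forward": 0, "absent": 1, "reverse": 2}
    }
  ]
}
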