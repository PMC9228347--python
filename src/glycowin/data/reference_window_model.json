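{
  "anchor_glycoform": "A2G2",
  "k": 3.0,
  "entries": {
    "A2G2F1": {
      "median": 1.032,
      "sigma": 0.0006666666666666673,
      "lower": 1.027,
      "upper": 1.034,
      "n_obs": null,
      "degenerate": false
    },
    "A3G3": {
      "median": 1.088,
      "sigma": 0.0043333333333333,
      "lower": 1.074,
      "upper": 1.101,
      "n_obs": null,
      "degenerate": false
    },
    "A3G3F1": {
      "median": 1.121,
      "sigma": 0.006333333333333302,
      "lower": 1.102,
      "upper": 1.14,
      "n_obs": null,
      "degenerate": false
    },
    "A2G2S1": {
      "median": 1.387,
      "sigma": 0.013333333333333345,
      "lower": 1.347,
      "upper": 1.427,
      "n_obs": null,
      "degenerate": false
    },
    "A2G2S2": {
      "median": 1.879,
      "sigma": 0.010999999999999973,
      "lower": 1.846,
      "upper": 1.912,
      "n_obs": null,
      "degenerate": false
    },
    "A2G2S1F1": {
      "median": 1.41,
      "sigma": 0.0076666666666667105,
      "lower": 1.388,
      "upper": 1.433,
      "n_obs": null,
      "degenerate": false
    },
    "A2G2S2F1": {
      "median": 1.892,
      "sigma": 0.026333333333333393,
      "lower": 1.813,
      "upper": 1.971,
      "n_obs": null,
      "degenerate": false
    },
    "A3G3S1": {
      "median": 1.447,
      "sigma": 0.024999999999999984,
      "lower": 1.372,
      "upper": 1.522,
      "n_obs": null,
      "degenerate": false
    },
    "A3G3S2": {
      "median": 1.953,
      "sigma": 0.02200000000000002,
      "lower": 1.886,
      "upper": 2.019,
      "n_obs": null,
      "degenerate": false
    },
    "A3G3S3": {
      "median": 2.307,
      "sigma": 0.024666666666666615,
      "lower": 2.232,
      "upper": 2.381,
      "n_obs": null,
      "degenerate": false
    }
  }
}
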