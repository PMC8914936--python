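{
  "provenance": "Bundled default reference library: per-action mean angle deltas (degrees) of the first and second motion units, three body parts x three Euler axes.",
  "actions": {
    "socks": {
      "upper_arm": {"roll": [0.15, 0.12], "pitch": [0.55, 0.10], "yaw": [-1.3, -0.15]},
      "lower_arm": {"roll": [0.60, 0.25], "pitch": [-0.55, 0.10], "yaw": [0.40, -0.30]},
      "hand": {"roll": [0.01, 0.20], "pitch": [-0.50, -0.15], "yaw": [-0.30, -0.52]}
    },
    "shoes": {
      "upper_arm": {"roll": [0.00, -0.35], "pitch": [0.70, 0.30], "yaw": [-1.2, 0.37]},
      "lower_arm": {"roll": [0.35, -0.30], "pitch": [-0.8, 0.60], "yaw": [0.45, 0.10]},
      "hand": {"roll": [0.10, 0.10], "pitch": [-0.60, 0.55], "yaw": [-0.10, 0.30]}
    },
    "laces": {
      "upper_arm": {"roll": [0.20, -0.20], "pitch": [0.60, 0.00], "yaw": [-1.30, -0.50]},
      "lower_arm": {"roll": [0.90, -0.30], "pitch": [-0.55, -0.10], "yaw": [0.15, -1.20]},
      "hand": {"roll": [0.20, -0.55], "pitch": [-0.73, -0.05], "yaw": [-0.10, -1.70]}
    }
  }
}
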