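{
  "version": 1,
  "description": "Spectral-profile presets for the synthetic BOLD generator. integration_sd drives the lambda=0 global mode (whole-cortex coherence), gradient_sd drives modes 2-3 (the smooth modular axes that functional gradients pick up), tail_sd/tail_decay shape the exponential profile over the remaining high-spatial-frequency modes (which carry harmonic energy), noise_sd is isotropic regional noise. Calibrated so the awake-like presets show wide gradients and high integration while the deep-anaesthesia-like presets show high structurally-weighted energy.",
  "presets": {
    "awake": {
      "integration_sd": 1.5,
      "gradient_sd": 1.0,
      "tail_sd": 0.25,
      "tail_decay": 3.0,
      "noise_sd": 0.3,
      "arousal_score": 11
    },
    "ct_high": {
      "integration_sd": 1.3,
      "gradient_sd": 0.85,
      "tail_sd": 0.3,
      "tail_decay": 2.5,
      "noise_sd": 0.3,
      "arousal_score": 9
    },
    "light_anaesthesia": {
      "integration_sd": 0.9,
      "gradient_sd": 0.6,
      "tail_sd": 0.4,
      "tail_decay": 1.5,
      "noise_sd": 0.3,
      "arousal_score": 3
    },
    "ct_low": {
      "integration_sd": 0.9,
      "gradient_sd": 0.6,
      "tail_sd": 0.4,
      "tail_decay": 1.5,
      "noise_sd": 0.3,
      "arousal_score": 3
    },
    "deep_anaesthesia": {
      "integration_sd": 0.4,
      "gradient_sd": 0.25,
      "tail_sd": 0.55,
      "tail_decay": 0.5,
      "noise_sd": 0.3,
      "arousal_score": 0
    },
    "dbs_off": {
      "integration_sd": 0.4,
      "gradient_sd": 0.25,
      "tail_sd": 0.55,
      "tail_decay": 0.5,
      "noise_sd": 0.3,
      "arousal_score": 0
    },
    "vt_low": {
      "integration_sd": 0.45,
      "gradient_sd": 0.28,
      "tail_sd": 0.53,
      "tail_decay": 0.55,
      "noise_sd": 0.3,
      "arousal_score": 0
    },
    "vt_high": {
      "integration_sd": 0.45,
      "gradient_sd": 0.28,
      "tail_sd": 0.53,
      "tail_decay": 0.55,
      "noise_sd": 0.3,
      "arousal_score": 0
    }
  }
}
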