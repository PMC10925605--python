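{
  "version": 1,
  "description": "Composite behavioural arousal score (0-11) per experimental condition, and the printed sub-scores where a full assessment is on record.",
  "condition_scores": {
    "awake": 11,
    "ketamine": 0,
    "light_propofol": 4,
    "deep_propofol": 0,
    "light_sevoflurane": 3,
    "deep_sevoflurane": 0,
    "light_anaesthesia": 3,
    "deep_anaesthesia": 0,
    "dbs_off": 0,
    "ct_low": 3,
    "ct_high": 9,
    "vt_low": 0,
    "vt_high": 0
  },
  "assessments": {
    "awake": {
      "exploration": 2,
      "spontaneous_movements": 2,
      "shaking_prodding": 2,
      "toe_pinch": 2,
      "eyes_opening": 2,
      "corneal_reflex": 1
    },
    "dbs_off": {
      "exploration": 0,
      "spontaneous_movements": 0,
      "shaking_prodding": 0,
      "toe_pinch": 0,
      "eyes_opening": 0,
      "corneal_reflex": 0
    },
    "ct_low": {
      "exploration": 0,
      "spontaneous_movements": 0,
      "shaking_prodding": 0,
      "toe_pinch": 1,
      "eyes_opening": 1,
      "corneal_reflex": 1
    },
    "ct_high": {
      "exploration": 1,
      "spontaneous_movements": 1,
      "shaking_prodding": 2,
      "toe_pinch": 2,
      "eyes_opening": 2,
      "corneal_reflex": 1
    }
  }
}
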