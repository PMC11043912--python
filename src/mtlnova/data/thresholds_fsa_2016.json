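{
  "name": "UK DH/FSA front-of-pack guidance (2016), per 100 g food / 100 ml drink",
  "thresholds": {
    "fat": {
      "food": {"low_max": 3.0, "high_min": 17.5},
      "drink": {"low_max": 1.5, "high_min": 8.75}
    },
    "satfat": {
      "food": {"low_max": 1.5, "high_min": 5.0},
      "drink": {"low_max": 0.75, "high_min": 2.5}
    },
    "sugar": {
      "food": {"low_max": 5.0, "high_min": 22.5},
      "drink": {"low_max": 2.5, "high_min": 11.25}
    },
    "salt": {
      "food": {"low_max": 0.3, "high_min": 1.5},
      "drink": {"low_max": 0.3, "high_min": 0.75}
    }
  }
}
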