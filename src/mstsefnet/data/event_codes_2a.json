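{
  "description": "Cue annotation codes for the 4-class (left hand / right hand / feet / tongue) GDF dialect",
  "codes": {"769": 0, "770": 1, "771": 2, "772": 3},
  "class_names": ["left_hand", "right_hand", "feet", "tongue"],
  "eeg_channels": 22
}
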