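{
  "description": "Cue annotation codes for the 2-class (left hand / right hand) GDF dialect",
  "codes": {"769": 0, "770": 1},
  "class_names": ["left_hand", "right_hand"],
  "eeg_channels": 3,
  "channels": ["C3", "Cz", "C4"]
}
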