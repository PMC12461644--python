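{
  "version": 1,
  "units": {
    "flip_angle": "degree",
    "echo_time": "ms",
    "repetition_time": "ms",
    "inversion_time": "ms",
    "magnetic_field_strength": "Tesla"
  },
  "ordinals": [
    "first", "second", "third", "fourth", "fifth",
    "sixth", "seventh", "eighth", "ninth", "tenth"
  ],
  "modality_names": {
    "MR": "magnetic resonance imaging",
    "MRI": "magnetic resonance imaging",
    "CT": "computed tomography",
    "CBCT": "cone beam computed tomography"
  },
  "lowercase_fields": ["organ", "plane"]
}
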