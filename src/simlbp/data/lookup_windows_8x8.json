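{
  "left_eye": {"rows": [2, 4], "cols": [1, 4]},
  "right_eye": {"rows": [2, 4], "cols": [4, 7]},
  "left_brow": {"rows": [1, 3], "cols": [1, 4]},
  "right_brow": {"rows": [1, 3], "cols": [4, 7]},
  "nose": {"rows": [3, 6], "cols": [3, 5]},
  "mouth": {"rows": [5, 7], "cols": [2, 6]}
}
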