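{
  "DYS448": ["P3_spacer"],
  "DYF387S1": ["y1", "y2"]
}
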