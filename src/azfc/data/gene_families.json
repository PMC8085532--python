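{
  "PRY": {"host_family": "b", "copies_per_segment": 1, "external_constant_copies": 0},
  "RBMY": {"host_family": "t", "copies_per_segment": 1, "external_constant_copies": 4},
  "BPY": {"host_family": "g", "copies_per_segment": 1, "external_constant_copies": 0},
  "DAZ": {"host_family": "r", "copies_per_segment": 1, "external_constant_copies": 0},
  "CDY": {"host_family": "y", "copies_per_segment": 1, "external_constant_copies": 0}
}
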