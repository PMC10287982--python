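{
  "schema_version": 1,
  "nucleotide": "GTP",
  "k_3on": {"estimate": 2.3, "error": 0.2, "units": "1/(uM*s)"},
  "k_3off": [
    {"rate": 1.3, "error": 0.1, "amplitude": 0.54, "units": "1/s"},
    {"rate": 0.30, "error": 0.02, "amplitude": 0.46, "units": "1/s"}
  ],
  "k_3BR": {"estimate": 3.2, "error": 0.5, "units": "1/s"},
  "k_1RD_plus": {"estimate": 0.69, "error": 0.02, "units": "1/s"},
  "k_31D": {"estimate": 4.0, "error": 1.0, "units": "1/s"}
}
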