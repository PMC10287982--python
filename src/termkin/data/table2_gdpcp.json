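{
  "schema_version": 1,
  "nucleotide": "GDPCP",
  "k_3on": {"estimate": 2.0, "error": null, "units": "1/(uM*s)"},
  "k_3off": [
    {"rate": 1.1, "error": 0.1, "amplitude": 0.56, "units": "1/s"},
    {"rate": 0.18, "error": 0.01, "amplitude": 0.44, "units": "1/s"}
  ],
  "k_3BR": {"estimate": 2.1, "error": 0.2, "units": "1/s"},
  "k_1RD_plus": {"estimate": 0.14, "error": 0.01, "units": "1/s"},
  "k_31D": {"estimate": 0.0164, "error": 0.004, "units": "1/s"}
}
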