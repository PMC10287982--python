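{
  "schema_version": 1,
  "nucleotide": "GDP",
  "k_3on": {"estimate": 2.0, "error": null, "units": "1/(uM*s)"},
  "k_3off": [
    {"rate": 4.6, "error": 0.7, "amplitude": 0.84, "units": "1/s"},
    {"rate": 0.25, "error": 0.09, "amplitude": 0.16, "units": "1/s"}
  ],
  "k_3BR": null,
  "k_1RD_plus": null,
  "k_31D": null
}
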