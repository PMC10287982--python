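{
  "schema_version": 1,
  "rf_id": "RF1",
  "temperature_C": 30,
  "k_ion": {"estimate": 21.0, "error": null, "units": "1/(uM*s)", "synthetic": true,
    "note": "not measured at 30C; 20C value carried over"},
  "k_iIA": {"estimate": 1.3, "error": 0.3, "units": "1/s"},
  "k_iAR_minus": {"estimate": 0.072, "error": 0.001, "units": "1/s"},
  "k_iAR_plus": {"estimate": 30.0, "error": null, "units": "1/s", "synthetic": true,
    "note": "not tabulated; any value >= 30 reproduces the ~0.8 s saturating rotation time at 30C"},
  "k_iRD_plus": {"estimate": 2.5, "error": 0.3, "units": "1/s"},
  "K3": {"estimate": 0.03, "error": null, "units": "uM", "synthetic": true}
}
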