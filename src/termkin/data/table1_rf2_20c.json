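{
  "schema_version": 1,
  "rf_id": "RF2",
  "temperature_C": 20,
  "k_ion": {"estimate": 10.5, "error": null, "units": "1/(uM*s)",
    "note": "UAA association referenced from earlier work"},
  "k_iIA": {"estimate": 0.09, "error": null, "units": "1/s",
    "note": "95% CI spans negative values; point fixture only, never a test target"},
  "k_iAR_minus": {"estimate": 0.04, "error": 0.03, "units": "1/s"},
  "k_iAR_plus": {"estimate": 3.0, "error": null, "units": "1/s",
    "note": "fixed in mean-rotation fits to the RF3-bound rotation rate"},
  "k_iRD_plus": {"estimate": 3.5, "error": 0.4, "units": "1/s"},
  "K3": {"estimate": 0.03, "error": null, "units": "uM", "synthetic": true}
}
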