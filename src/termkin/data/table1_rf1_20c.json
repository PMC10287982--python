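{
  "schema_version": 1,
  "rf_id": "RF1",
  "temperature_C": 20,
  "k_ion": {"estimate": 21.0, "error": 2.0, "units": "1/(uM*s)"},
  "k_iIA": {"estimate": 0.034, "error": 0.007, "units": "1/s"},
  "k_iAR_minus": {"estimate": 0.027, "error": 0.005, "units": "1/s"},
  "k_iAR_minus_text": {"estimate": 0.04, "error": null, "units": "1/s",
    "note": "alternative point estimate quoted in running text; table value above is authoritative"},
  "k_iAR_plus": {"estimate": 3.0, "error": null, "units": "1/s",
    "note": "fixed in mean-rotation fits to the RF3-bound rotation rate"},
  "k_iRD_plus": {"estimate": 0.76, "error": 0.14, "units": "1/s"},
  "K3": {"estimate": 0.03, "error": null, "units": "uM", "synthetic": true,
    "note": "not tabulated; assumed mid-titration value consistent with saturation below ~0.2 uM RF3"}
}
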