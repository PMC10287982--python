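{
  "free": [
    "RF1",
    "RF2",
    "RF3_GDP",
    "RF3_apo",
    "RF3_GTP"
  ],
  "n_reactions": 62,
  "n_species": 44,
  "species": {
    "UAA": [
      "R_E",
      "R_I",
      "R_A",
      "R_P",
      "R_PR3",
      "RA_F_RF1",
      "RP_F_RF1",
      "RP_F3D_RF1",
      "RP_F3N_RF1",
      "RP_F3T_RF1",
      "RPR_F3_RF1",
      "RA_F_RF2",
      "RP_F_RF2",
      "RP_F3D_RF2",
      "RP_F3N_RF2",
      "RP_F3T_RF2",
      "RPR_F3_RF2"
    ],
    "UAG": [
      "R_E",
      "R_I",
      "R_A",
      "R_P",
      "R_PR3",
      "RA_F_RF1",
      "RP_F_RF1",
      "RP_F3D_RF1",
      "RP_F3N_RF1",
      "RP_F3T_RF1",
      "RPR_F3_RF1"
    ],
    "UGA": [
      "R_E",
      "R_I",
      "R_A",
      "R_P",
      "R_PR3",
      "RA_F_RF2",
      "RP_F_RF2",
      "RP_F3D_RF2",
      "RP_F3N_RF2",
      "RP_F3T_RF2",
      "RPR_F3_RF2"
    ]
  }
}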