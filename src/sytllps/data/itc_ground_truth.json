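{
  "_comment": "Ground-truth sequential-site Ca2+ binding parameters used to generate synthetic ITC titrations for parameter-recovery studies. Stepwise dissociation constants (kd_um, micromolar) are the published ITC estimates for the three syt1 cytoplasmic-domain constructs. Per-step enthalpies (dh_kcal, kcal/mol) are SYNTHETIC fixture values chosen by this package: single-sign magnitudes 2-10 kcal/mol per construct (endothermic for the two wild-type-linker constructs, exothermic for the JuxtaK mutant, matching the sign of the measured reaction heats). Mixed endo-/exothermic per-step enthalpies are deliberately not used: cancelling heats flatten the titration curve and destroy affinity identifiability, which is exactly why the linker-less construct could not be fitted.",
  "syt1_c2ab_80_421": {
    "n_sites": 5,
    "kd_um": [
      80.0,
      190.0,
      309.0,
      1310.0,
      2900.0
    ],
    "dh_kcal": [
      4.0,
      5.0,
      6.0,
      7.0,
      8.0
    ]
  },
  "syt1_c2ab_96_421": {
    "n_sites": 5,
    "kd_um": [
      23.5,
      210.0,
      250.0,
      451.0,
      2510.0
    ],
    "dh_kcal": [
      4.0,
      5.0,
      6.0,
      7.0,
      8.0
    ]
  },
  "syt1_c2ab_80_juxtak_421": {
    "n_sites": 4,
    "kd_um": [
      14.1,
      24.2,
      156.0,
      925.0
    ],
    "dh_kcal": [
      -3.0,
      -5.0,
      -7.0,
      -9.0
    ]
  }
}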