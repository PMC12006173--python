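{
  "_comment": "Literal reference values, transcribed independently of the config loader.",
  "k_pCaM4_per_s": 0.96,
  "k_pCaMpartial_per_s": 0.1,
  "kcat_pp1_per_s": 11.5,
  "KM_pp1_uM": 11.0,
  "koff_CaM4_la_per_s": 6.6,
  "koff_CaM4_ha_per_s": 9e-05,
  "KD_CaM4_la_nM": 65.0,
  "V_spine_fL": 0.016,
  "V_psd_fL": 0.002915,
  "conc_CaM_total_uM": 30.0,
  "conc_PP1_uM": 1.25,
  "ca_baseline_nM": 100.0,
  "n_holoenzymes": 60,
  "n_subunits": 720,
  "stimulus": {
    "epochs": 2,
    "bursts_per_epoch": 5,
    "aps_per_burst": 5,
    "burst_rate_hz": 5.0,
    "ap_rate_hz": 50.0,
    "t_start_s": 1.0,
    "n_docked_init": 7,
    "redock_rate_per_s": 0.2,
    "p_release_init": 0.2,
    "n_nmdar": 15,
    "bap_delay_ms": 10.0
  }
}
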