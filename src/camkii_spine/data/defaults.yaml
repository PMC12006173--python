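# Default model parameters.
#
# Units are stated in each key name (s^-1, M^-1 s^-1, uM, nM, fL) and are
# converted to SI internally.  Every value can be overridden by a user config
# file or keyword overrides; the fully resolved set is logged per run.

volumes:
  V_spine_fL: 0.016          # spine cytosol
  V_psd_fL: 0.002915         # PSD capsule nested in the spine
  reservoir_diameter_um: 0.7 # dendritic-shaft cylinder (treated as a clamped bath)
  reservoir_length_um: 1.5

concentrations:
  conc_CaM_total_uM: 30.0
  conc_PP1_uM: 1.25          # swept 0.65 - 5.0 in the phosphatase-sensitivity runs
  ca_baseline_nM: 100.0

counts:
  n_holoenzymes: 60          # 6.67 uM holoenzyme = 80 uM subunits in 0.016 fL

kinase:
  k_pCaM4: 0.96              # s^-1, both neighbours CaM4-loaded (or kinase pT286)
  k_pCaMpartial: 0.1         # s^-1, all other active neighbour permutations
  KD_CaM4_la_nM: 65.0        # initial (low-affinity) CaM4 binding
  koff_CaM4_la: 6.6          # s^-1
  koff_CaM4_ha: 9.0e-5       # s^-1, trapped state

pp1:
  kcat: 11.5                 # s^-1
  KM_uM: 11.0
  koff_policy: kcat          # kon = (koff + kcat)/KM with koff set by policy

# Ca2+ binding to each lobe of calmodulin, two sequential sites per lobe,
# in two contexts: free CaM and CaM bound to a CaMKII subunit.  The trapped
# (ha) context defaults to the bound (la) values (null = copy), so the entire
# trapping effect is carried by the CaM off-rate from the kinase.
# Provenance: source model of Ca2+/CaM/CaMKII kinetics (transcribed);
# measured ~30 C.
cam_ca_rates:
  free:
    C: {kon1: 6.8e6,  koff1: 68.0,   kon2: 6.8e6,  koff2: 10.0}
    N: {kon1: 1.08e8, koff1: 4150.0, kon2: 1.08e8, koff2: 800.0}
  camkii_la:
    C: {kon1: 4.4e7,  koff1: 33.0,   kon2: 4.4e7,  koff2: 0.8}
    N: {kon1: 7.6e7,  koff1: 300.0,  kon2: 7.6e7,  koff2: 20.0}
  camkii_ha: null

# Association-rate anchors for CaM species binding the kinase.  Only the
# RATIOS are used: per-species on-rates are interpolated geometrically in
# lobe occupancy and renormalised so kon(CaM4) = koff_CaM4_la / KD_CaM4_la.
# Off-rates then follow from detailed balance (see cam.build_rate_tables).
cam_binding_kon_anchors_M_s:
  CaM0: 3.8e3
  CaM2C: 9.2e5
  CaM2N: 1.2e5
  CaM4: 3.0e7

stimulus:
  epochs: 2
  bursts_per_epoch: 5
  aps_per_burst: 5
  burst_rate_hz: 5.0
  ap_rate_hz: 50.0
  t_start_s: 1.0
  epoch2_onset_s: 5.0
  p_release_init: 0.2        # compound probability of >=1 vesicle per AP, initial
  n_docked_init: 7
  redock_rate: 0.2           # s^-1 per empty site
  facilitation_increment: 0.25
  facilitation_tau_s: 0.25
  n_nmdar: 15
  bap_delay_s: 0.010
  coincidence_window_s: 0.020
  p_open: 0.5                # per glutamate-bound receptor, given a coincident bAP
  n_ca_per_opening: 250      # calibrated, not measured (see docs/methods.md)
  pulse_tau_s: 0.005
  refractory_s: 0.0          # per-receptor desensitisation, 0 = off

calcium:
  tau_ca_clear_s: 0.015      # calibrated, not measured: effective clearance to baseline

exchange:
  k_cam_exchange: 10.0       # s^-1 relaxation of spine free CaM toward the bath

flags:
  trapping: false
  competition: false
  psd_localization: "off"    # off | camkii_only | camkii_and_pp1
  ha_revert_on_dephos: true
  trapped_rebind: "la"     # affinity mode for CaM rebinding to an emptied
                           # trapped site: la (default) or ha
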