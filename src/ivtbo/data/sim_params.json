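{
 "dsrna_onset_min": 115.0,
 "dsrna_rho_inf": 0.0504950359131136,
 "dsrna_tau_min": 40.0,
 "factors": {
  "DNA_nM": {
   "K": 20.000000000412523,
   "floor": 0.55,
   "h": 3.1671028381874353
  },
  "DTT_mM": {
   "K": 3.1109709515989814,
   "floor": 0.6,
   "h": 4.9999413247611075
  },
  "NTPs_mM": {
   "K": 3.0000000000000004,
   "floor": 0.5,
   "h": 4.409814154389496
  },
  "PPase_UmL": {
   "K": 0.5000000000000001,
   "floor": 0.6,
   "h": 3.6033226626357253
  },
  "T7_UmL": {
   "center": 3.8180205203794775,
   "floor": 0.4,
   "wl": 0.42944924028842796,
   "wr": 0.2347692302768416
  },
  "cofactor_mM": {
   "center": 47.611032512946736,
   "floor": 0.2,
   "mgcl2_shift": 15.0,
   "wl": 16.10860307078068,
   "wr": 19.894767531612114
  },
  "pH": {
   "center": 6.700699710829507,
   "floor": 0.45,
   "wl": 0.15000000000000002,
   "wr": 0.7999999999999999
  },
  "spermidine_mM": {
   "center": 1.352529768516418,
   "floor": 0.3,
   "wl": 1.6847761347325212,
   "wr": 3.4453104101843945
  },
  "temperature_C": {
   "center": 40.846504022553106,
   "floor": 0.4,
   "w": 8.817644597080958
  }
 },
 "kin_scale": 0.8775206781707471,
 "noise_sd": 0.5,
 "template_amp_rate": 1.5103315168498176e-05,
 "template_bp_threshold": 2000.0,
 "template_slope_rate": 3.819440188507736e-07,
 "y_max": 16.999999999999996
}
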