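# Reference parameter set: calibrated once against the waypoint kinetic
# features of maximally stimulated fibroblasts (see docs/methods.md and
# scripts/derive_theta_ref.py), then frozen. Nuclear-dominant buffering
# regime: B_n = 20, B_c = 0.3.
observation:
  rho_c: 0.111889
  rho_e: 0.2
  rho_n: 0.199791
params:
  M2_const: 0.0
  S_basal: 0.02
  Sc_tot: 0.1
  Sn_tot: 6.061169
  a_E1: 5.170973
  a_E2: 5.170973
  a_M: 0.54562
  d_M: 0.273699
  d_c1: 0.189957
  d_c2: 0.947811
  d_n1: 5.321529
  d_n2: 1.538135
  k_cat_c: 0.3
  k_cat_n: 0.373516
  k_fb: 11.29971
  k_in: 3.593257
  k_off_c: 1.0
  k_off_n: 0.115664
  k_on_c: 3.12
  k_on_n: 0.322829
  k_out: 1.283329
  k_pass: 0.553896
  k_rec: 0.121266
  k_rel: 100.0
  k_sdp_c: 0.2
  k_sdp_n: 0.001025
  phi_n: 0.2
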