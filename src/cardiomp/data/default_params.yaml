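cell:
  myocardial:
    A: 100.0
    B: -80.0
    a: 0.12
    k1: 8.0
    k2: 0.08999312050197938
    Cm: 1.0
    beta_sv: 1000.0
    eps0: 0.00017998624100395877
    mu1: 0.017998624100395877
    mu2: 0.3
    k_Ta: 60.0
    eps0_act: 0.01
    epsinf_act: 0.1
    xi: 0.1
    V_threshold: 0.0
    rho_i: 0.2
    R_pmj: 1.0
    literal_recovery: false
  purkinje:
    A: 100.0
    B: -80.0
    a: 0.07
    k1: 8.0
    k2: 0.1648983177164552
    Cm: 1.0
    beta_sv: 1000.0
    eps0: 0.00013498968075296907
    mu1: 0.013498968075296908
    mu2: 0.3
    k_Ta: 60.0
    eps0_act: 0.01
    epsinf_act: 0.1
    xi: 0.1
    V_threshold: 0.0
    rho_i: 0.20523184496606395
    R_pmj: 1.0
    literal_recovery: false
  achieved:
    cv_ratio: 2.9997629143929103
    upstroke_ratio_clamped: 1.9999899245838684
    upstroke_ratio_cable: 2.0636606727658666
    cv_myocardial_cm_ms: 0.05999969644082196
    cv_purkinje_cm_ms: 0.17998486425801002
tissue:
  sigma_f: 17.54576004788136
  sigma_s: 8.77288002394068
  sigma_n: 4.38644001197034
  cv_target_cm_ms: 0.06
circulation:
  R_sys: 1.1682295023563263
  C_sa: 1.3955636804508822
  R_pul: 0.08123896698972559
  C_pa: 2.6387358097386833
  V0_sv: 3053.4197281430315
  V0_pv: 211.67966183768792
  init_volumes:
    sa: 603.891512888346
    sv: 3080.438761562608
    pa: 125.71451584413154
    pv: 241.75972714137393
    la: 118.30286181546265
    ra: 64.86006188936692
chambers:
  lv:
    V0: 15.0
    c1: 0.79
    c2: 0.02
    k_act: 0.03744039329635636
    V_inf: 148.39
  rv:
    V0: 10.0
    c1: 0.65
    c2: 0.015
    k_act: 0.008893037216202751
    V_inf: 144.7
heart_failure:
  k_ta_scale: 0.5
  heart_rate: 80.0
  lv_dilation_ml: 158.34357586566816
  passive_slope_scale: 0.9999999999993776
  extra_volume_ml: 1.7411837007201992e-10
  edv_target: 299.0
pump:
  k_e: 0.025
  R_pump: 1.0
  L: 0.01
  J: 0.0001
  a_p: 1.0e-06
  b_p: 3.0e-08
  c_p: 0.0001
  d_p: 5.0e-10
  e_p: 0.0
  f_p: -0.2533557155299545
  g_p: 0.0022038439573193575
  L_io: 0.1
  k_r: 0.9999995832926838
  R_cannula: 0.5
  k_pump: -20.0
  omega_set_rpm: 2100.0
  literal_emf_sign: true
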