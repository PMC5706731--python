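mitral:
  ra_ohm_cm: 70.0
  tau_ks_ms: 10.0
  e_na_mv: 50.0
  e_k_mv: -90.0
  nap_vhalf_mv: -50.0
  nap_k_mv: 5.0
  ks_vhalf_mv: -42.1475
  ks_k_mv: 5.5282
  soma:
    length_um: 25.0
    diam_um: 20.0
    cm_uf_cm2: 1.2
    e_leak_mv: -62.1419
    channels:
      na: 100.0
      kdr: 80.0
      leak: 0.5831
      nap: 0.217
      ks: 1.1347
      ahp: 1.6
  tuft:
    length_um: 20.0
    diam_um: 4.0
    cm_uf_cm2: 1.2
    e_leak_mv: -62.1419
    channels:
      na: 20.0
      kdr: 20.0
      leak: 0.5831
      nap: 0.217
      ks: 1.1347
  dendrite:
    n: 7
    total_length_um: 500.0
    diam_um: 3.4
    cm_uf_cm2: 1.2
    e_leak_mv: -62.1419
    channels:
      na: 60.0
      kdr: 40.0
      leak: 0.5831
      nap: 0.217
      ks: 1.1347
  spike_shift_mv: 10.0
  ahp_vhalf_mv: -20.0
  ahp_k_mv: 5.0
  ahp_tau_on_ms: 5.0
  ahp_tau_off_ms: 172.3518
granule:
  neck_g_ns: 1.0
  e_na_mv: 50.0
  e_k_mv: -90.0
  body:
    length_um: 12.0
    diam_um: 10.0
    cm_uf_cm2: 1.0
    e_leak_mv: -67.0
    channels:
      na: 60.0
      kdr: 40.0
      leak: 0.85
      ahp: 1.0
  spine:
    length_um: 1.0
    diam_um: 1.0
    cm_uf_cm2: 1.0
    e_leak_mv: -67.0
    channels:
      leak: 0.2
  spike_shift_mv: 10.0
  ahp_tau_off_ms: 100.0
periglomerular:
  neck_g_ns: 4.0
  e_na_mv: 50.0
  e_k_mv: -90.0
  body:
    length_um: 12.0
    diam_um: 10.0
    cm_uf_cm2: 1.0
    e_leak_mv: -65.0
    channels:
      na: 60.0
      kdr: 40.0
      leak: 2.5
  spine:
    length_um: 1.0
    diam_um: 1.0
    cm_uf_cm2: 1.0
    e_leak_mv: -65.0
    channels:
      leak: 0.2
  spike_shift_mv: 10.0
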