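schema_version: 1
name: NORMAL
description: Healthy resting circulation (calibration baseline)
heart:
  HR: 80.0
  LA:
    E_es: 0.3
    E_min: 0.15
    V0: 8.0
    edpvr_alpha: 0.8
    edpvr_beta: 0.04
    t_activation_onset: 0.85
    t_activation_duration: 0.17
  LV:
    E_es: 1.6
    E_min: 0.08
    V0: 5.0
    edpvr_alpha: 0.18
    edpvr_beta: 0.015
    t_activation_onset: 0.0
    t_activation_duration: 0.36
  RA:
    E_es: 0.22
    E_min: 0.12
    V0: 8.0
    edpvr_alpha: 0.32
    edpvr_beta: 0.06
    t_activation_onset: 0.85
    t_activation_duration: 0.17
  RV:
    E_es: 0.5
    E_min: 0.05
    V0: 5.0
    edpvr_alpha: 0.1
    edpvr_beta: 0.0225
    t_activation_onset: 0.0
    t_activation_duration: 0.36
circuit:
  SVR_WU: 16.0
  PVR_WU: 0.8
  svr_split:
    SA: 0.71
    SC: 0.23
    SV: 0.06
  pvr_split:
    PA: 0.5
    PC: 0.4
    PV: 0.1
  zc_fraction_systemic: 0.045
  zc_fraction_pulmonary: 0.68
  compliances:
    C_SA: 3.0
    C_SC: 3.0
    C_SV: 20.0
    C_PA: 13.0
    C_PC: 4.2
    C_PV: 5.7
  valves:
    R_MV: 0.004
    R_AV: 0.08
    R_TV: 0.005
    R_PAV: 0.005
    A_MV: 4.0
    A_AV: 4.0
    A_TV: 5.0
    A_PAV: 3.5
  V_total: 795.0
  rho: 1.05
initial:
  V_LA: 40.0
  V_LV: 110.0
  V_RA: 40.0
  V_RV: 100.0
engine:
  dt: 0.0002
  decimation: 5
  volume_floor: 1.0
devices:
  limiter_gain: 1.0
  hq_table: default
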