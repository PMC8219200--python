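# Plume and particle characteristics of the two extrafine fixed-combination
# pMDI products (per actuation).  Velocities are plume ejection velocities
# measured at 10 mm (actuator exit) and 100 mm (throat distance).
# FPF is expressed as a fraction of the delivered dose (DD); the nominal GB
# dose per actuation is a configurable assumption (12.5 ug).
products:
  BDP/FF/GB:
    plume:
      shot_mass_g: 0.073
      cone_angle_deg: 21.24
      velocity_10mm_m_s: 21.0
      velocity_100mm_m_s: 6.0
      duration_ms: 229.4
    apis:
      - {name: BDP, nominal_dose_ug: 100.0, delivered_dose_ug: 87.0, mmad_um: 1.1, gsd: 2.0, fpf: 0.43}
      - {name: FF, nominal_dose_ug: 6.0, delivered_dose_ug: 5.0, mmad_um: 1.1, gsd: 2.0, fpf: 0.44}
      - {name: GB, nominal_dose_ug: 12.5, delivered_dose_ug: 11.0, mmad_um: 1.1, gsd: 2.0, fpf: 0.42}
  BDP/FF:
    plume:
      shot_mass_g: 0.058
      cone_angle_deg: 15.61
      velocity_10mm_m_s: 11.4
      velocity_100mm_m_s: 5.1
      duration_ms: 169.0
    apis:
      - {name: BDP, nominal_dose_ug: 100.0, delivered_dose_ug: 85.0, mmad_um: 1.3, gsd: 2.4, fpf: 0.42}
      - {name: FF, nominal_dose_ug: 6.0, delivered_dose_ug: 5.0, mmad_um: 1.3, gsd: 2.1, fpf: 0.42}
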