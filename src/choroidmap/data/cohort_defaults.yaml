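# Default synthetic-cohort parameters: per-sector choroidal thickness
# (mean, SD) in micrometres and axial length (mean, SD) in millimetres for
# the low / moderate / high myopia groups, with the refractive-error
# sampling range in diopters.  Superior/inferior sectors (SIM, IIM, SOM,
# IOM), for which no published group statistics exist, default to the mean
# of the same-ring nasal and temporal entries.
groups:
  low:
    ct_um:
      Fovea: [273.85, 49.01]
      NIM: [239.64, 57.93]
      SIM: [250.395, 54.775]
      TIM: [261.15, 51.62]
      IIM: [250.395, 54.775]
      NOM: [180.65, 58.25]
      SOM: [207.45, 50.26]
      TOM: [234.25, 42.27]
      IOM: [207.45, 50.26]
    iol_mm: [24.619, 0.016]
    refractive_range_d: [-3.0, -0.25]
  moderate:
    ct_um:
      Fovea: [180.0, 28.25]
      NIM: [139.96, 31.53]
      SIM: [167.45, 29.655]
      TIM: [194.94, 27.78]
      IIM: [167.45, 29.655]
      NOM: [100.84, 16.75]
      SOM: [142.07, 20.565]
      TOM: [183.3, 24.38]
      IOM: [142.07, 20.565]
    iol_mm: [25.413, 0.022]
    refractive_range_d: [-5.75, -3.25]
  high:
    ct_um:
      Fovea: [139.54, 32.68]
      NIM: [105.02, 34.14]
      SIM: [133.235, 29.685]
      TIM: [161.45, 25.23]
      IIM: [133.235, 29.685]
      NOM: [86.64, 42.6]
      SOM: [124.82, 38.745]
      TOM: [163.0, 34.89]
      IOM: [124.82, 38.745]
    iol_mm: [25.983, 0.021]
    refractive_range_d: [-9.0, -6.0]
n_eyes:
  low: 20
  moderate: 10
  high: 10
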