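# Pi-titration protocol: glutamate/malate-energized, Pi-depleted
# mitochondria, state 2 / state 3. Version 1.
name: bose
version: 1
buffer:
  KCl: 0.125
  NaCl: 0.015
  K-Hepes: 0.020
  KEGTA: 0.001
  K2EDTA: 0.001
  MgCl: 0.005
  TPP: 4.0e-6        # probe, not modeled
pH: 7.1
temperature_C: 37
osmolarity_Osm: 0.300
load_mg_per_mL: 1.0
free_Ca_clamp_M: 550.0e-9
initialization: de_energized_equilibrated
matrix_K_mM: 125      # used with the rapid-equilibrium mKHE variant
pi_depletion: true
khe_variant: rapid_equilibrium
schedule:
  - {t_min: 0.0, action: add, GLU: 0.005, MAL: 0.005}
  - {t_min: 1.0, action: add, Pi: titrated 0-10 mM}
  - {t_min: 2.0, action: add, ADP: 0.0013, only: state3}
  - {t_min: 2.5, action: record}
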