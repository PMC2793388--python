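# TCA-intermediate dynamics protocol, pyruvate(/malate) energized.
# Version 1.
name: lanoue
version: 1
buffer:
  KCl: 0.150
  Tris-Cl: 0.020
  KPi: 0.020
  MgCl2: 0.005
  GLC: 0.030
pH: 7.2
temperature_C: 28
osmolarity_Osm: 0.370
load_mg_per_mL: 3.5   # inferred from the 1430 nmol/mg malate content
initialization: de_energized_nonequilibrated
preincubation_min: 0.5
schedule:
  - {t_min: 0.0, action: add, PYR: 0.002, MAL: 0.005, variant: pyr_mal}
  - {t_min: 0.0, action: add, PYR: 0.001, variant: pyr}
  - {t_min: 0.0, action: add, ADP: 0.0005, only: state3, note: HK trap active}
  - {t_min: 8.0, action: record}
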