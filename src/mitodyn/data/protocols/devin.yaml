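# Osmolarity-variation protocol, glutamate/malate energized KCl medium.
# Version 1.
name: devin
version: 1
buffer:
  Tris-HCl: 0.020
  EGTA: 0.001
  Tris-glutamate: 0.006
  Tris-malate: 0.006
  Tris-Pi: 0.005
  TPMP: 5.0e-6       # probes, not modeled
  DMO: 5.0e-6
  manitol: 5.0e-6
pH: 7.2
temperature_C: 26
osmolarity_Osm: varied          # [K+] = osmolarity / 2
load_mg_per_mL: 0.1             # adjusted load
adenylate_kinase: off           # no divalent cation in the medium
initialization: energized_equilibrated
schedule:
  - {t_min: 0.0, action: equilibrate, note: state 2, 5 min}
  - {t_min: 5.0, action: add, ADP: 0.001}
  - {t_min: 15.0, action: record, note: pseudo-steady state}
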