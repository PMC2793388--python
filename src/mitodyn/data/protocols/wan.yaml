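# Steady-state matrix calcium protocol, ATP-energized. Version 1.
name: wan
version: 1
buffer:
  KCl: 0.130
  HEPES: 0.020
  MgCl2: 0.005
  ATP: 0.005
  KH2PO4: 0.005
  NaCl: 0.005        # titrated 2 / 5 / 20 mM
  EGTA: 0.001
pH: 7.0
temperature_C: 28
osmolarity_Osm: 0.300
load_mg_per_mL: 2.0
initialization: energized_equilibrated
schedule:
  - {t_min: 0.0, action: clamp_free_ca, value: titrated}
  - {t_min: 2.0, action: record, note: steady matrix free Ca2+}
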