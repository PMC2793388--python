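# Matrix swelling protocol, succinate-energized K-salt medium. Version 1.
name: kowaltowski
version: 1
buffer:
  KCl: 0.135
  SUC: 0.005
  Pi: 0.0025
  EGTA: 1.0e-4
  MgCl2: 5.0e-4
pH: 7.2
temperature_C: 28
osmolarity_Osm: 0.290
load_mg_per_mL: 0.1
initialization: de_energized_nonequilibrated
interventions:
  oligomycin: {set_param: [F1FO, V], value: 0.0}
  diazoxide: {set_param: [mKATP, rho_endo], value: 0.0}
  five_hd: {set_param: [mKATP, g], value: 0.0}
conditions:
  atp_oligo: {ATP: 2.0e-4, oligomycin: true}
  atp_adp: {ATP: 2.0e-4, ADP: 1.0e-3}
  atp_oligo_adp: {ATP: 2.0e-4, ADP: 1.0e-3, oligomycin: true}
  noatp_oligo: {oligomycin: true}
  atp_adp_dzx: {ATP: 2.0e-4, ADP: 1.0e-3, diazoxide: true}
  atp_adp_dzx_5hd: {ATP: 2.0e-4, ADP: 1.0e-3, diazoxide: true, five_hd: true}
schedule:
  - {t_min: 0.0, action: add, note: condition species}
  - {t_min: 10.0, action: record, note: volume trajectory}
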