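# Reaction-specific activation energies (J/mol) used for Arrhenius
# temperature correction over the linear 4-37 C range; reactions absent
# from this table fall back to the standard Q10 = 2.25 correction.
# Values compiled from calorimetric/kinetic literature on the respective
# cardiac/liver mitochondrial enzymes.
reaction	Ea
PDH	5.8e4
CS	5.4e4
SDH	3.3e4
FH	3.6e4
MDH	6.2e4
CI	4.7e4
CIII	4.5e4
CIV	5.6e4
F1FO	6.0e4
ANT	7.6e4
PIC	5.2e4
CaUNI	4.0e4
HK	5.0e4
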