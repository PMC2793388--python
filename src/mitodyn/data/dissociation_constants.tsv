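# Dissociation constants (M) at 25 C, ionic strength ~0.1 M.
# H1/H2 are the first/second proton association sites that matter near
# physiological pH (unlisted sites are treated as non-binding).
# "inf" marks a cation that the ligand does not appreciably bind.
# Values compiled from standard stability-constant collections
# (NIST SRD 46 and common usage in mitochondrial/cardiac modeling).
ligand	KH1	KH2	KK	KNa	KMg	KCa
ATP	3.31e-7	1.00e-4	7.8e-2	5.0e-2	6.46e-5	1.00e-4
ADP	4.17e-7	1.00e-4	1.3e-1	1.0e-1	5.62e-4	8.00e-4
AMP	5.13e-7	1.00e-4	1.8e-1	1.8e-1	1.20e-2	1.50e-2
GTP	3.31e-7	1.00e-4	7.8e-2	5.0e-2	6.46e-5	1.00e-4
GDP	4.17e-7	1.00e-4	1.3e-1	1.0e-1	5.62e-4	8.00e-4
Pi	1.78e-7	7.00e-3	5.5e-1	5.5e-1	1.90e-2	7.00e-3
EGTA	3.98e-10	1.62e-9	inf	inf	5.20e-6	1.38e-11
EDTA	6.46e-11	7.41e-7	1.6e-1	4.2e-2	1.41e-9	2.45e-11
CIT	2.34e-6	5.01e-5	6.0e-1	6.0e-1	4.27e-4	3.20e-4
ISOC	2.34e-6	5.01e-5	6.0e-1	6.0e-1	4.27e-4	3.20e-4
MAL	2.00e-5	inf	inf	inf	2.80e-2	3.50e-2
SUC	5.75e-6	inf	inf	inf	5.00e-2	6.00e-2
FUM	7.94e-5	inf	inf	inf	1.0e-1	1.0e-1
aKG	2.00e-5	inf	inf	inf	1.1e-1	1.1e-1
GLU	5.62e-5	inf	inf	inf	1.7e-1	1.7e-1
ASP	2.51e-4	inf	inf	inf	1.4e-1	1.4e-1
PYR	3.16e-3	inf	inf	inf	inf	inf
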