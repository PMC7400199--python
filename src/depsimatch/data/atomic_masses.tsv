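# Monoisotopic atomic masses in Da (IUPAC/CODATA recommended values).
# The "e-" row is the electron mass, subtracted once per positive charge
# when converting a neutral adduct formula to a cation mass.
# version: 1
element	monoisotopic_mass_da
C	12.0
H	1.00782503207
N	14.0030740048
O	15.9949146196
Na	22.9897692809
e-	0.00054857990907
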