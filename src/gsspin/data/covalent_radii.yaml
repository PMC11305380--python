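# Covalent radii (angstrom) from the statistical analysis of experimental
# crystal structures by Cordero et al. (Dalton Trans., 2008, 2832).
# One value per element; for Mn/Fe/Co, where that analysis distinguishes
# spin states, the low-spin value is used so that the relative metal radius
# reads as an elongation relative to a strong-field bond.
H: 0.31
B: 0.84
C: 0.76
N: 0.71
O: 0.66
F: 0.57
Si: 1.11
P: 1.07
S: 1.05
Cl: 1.02
Ge: 1.20
As: 1.19
Se: 1.20
Br: 1.20
Sb: 1.39
Te: 1.38
I: 1.39
Cr: 1.39
Mn: 1.39
Fe: 1.32
Co: 1.26
Ni: 1.24
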