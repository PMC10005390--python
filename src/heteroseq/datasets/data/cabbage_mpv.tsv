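hybrid	heterosis_level	mpv
AE	middle	87.25
AF	strong	227.83
AG	middle	72.65
AH	weak	25.51
BE	middle	84.36
BF	middle	112.74
BG	weak	28.63
BH	weak	15.69
CE	strong	141.44
CF	strong	146.32
CG	middle	105.44
CH	middle	97.09
DE	strong	233.98
DF	middle	121.61
DG	middle	62.37
DH	weak	30.09
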