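element,radius
H,0.31
He,0.28
Li,1.28
Be,0.96
B,0.84
C,0.76
N,0.71
O,0.66
F,0.57
Ne,0.58
Na,1.66
Mg,1.41
Al,1.21
Si,1.11
P,1.07
S,1.05
Cl,1.02
Ar,1.06
K,2.03
Ca,1.76
Ti,1.60
Cr,1.39
Mn,1.39
Fe,1.32
Co,1.26
Ni,1.24
Cu,1.32
Zn,1.22
Ga,1.22
Ge,1.20
As,1.19
Se,1.20
Br,1.20
Mo,1.54
Ru,1.46
Rh,1.42
Pd,1.39
Ag,1.45
Sn,1.39
Sb,1.39
Te,1.38
I,1.39
Ir,1.41
Pt,1.36
Au,1.36
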