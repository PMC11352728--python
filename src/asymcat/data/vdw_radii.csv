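element,radius
H,1.20
He,1.40
Li,1.82
B,1.92
C,1.70
N,1.55
O,1.52
F,1.47
Ne,1.54
Na,2.27
Mg,1.73
Al,1.84
Si,2.10
P,1.80
S,1.80
Cl,1.75
Ar,1.88
K,2.75
Ca,2.31
Ni,1.63
Cu,1.40
Zn,1.39
Ga,1.87
Ge,2.11
As,1.85
Se,1.90
Br,1.85
Ru,2.00
Rh,2.00
Pd,1.63
Ag,1.72
Sn,2.17
Sb,2.06
Te,2.06
I,1.98
Ir,2.00
Pt,1.75
Au,1.66
Fe,2.00
Co,2.00
Mn,2.00
Cr,2.00
Ti,2.00
Mo,2.00
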