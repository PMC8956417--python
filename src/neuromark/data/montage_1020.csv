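label,x,y
Fp1,-0.27,0.85
Fp2,0.27,0.85
F7,-0.73,0.55
F3,-0.35,0.45
Fz,0.00,0.45
F4,0.35,0.45
F8,0.73,0.55
T3,-0.90,0.00
C3,-0.45,0.00
Cz,0.00,0.00
C4,0.45,0.00
T4,0.90,0.00
T5,-0.73,-0.55
P3,-0.35,-0.45
Pz,0.00,-0.45
P4,0.35,-0.45
T6,0.73,-0.55
O1,-0.27,-0.85
O2,0.27,-0.85
A1,-0.95,-0.05
A2,0.95,-0.05
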