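Hospital ID,x_km,y_km
A,9.0,11.0
B,11.0,13.0
C,15.0,16.0
D,18.0,14.0
E,30.0,25.0
F,12.0,20.0
G,42.0,35.0
H,25.0,8.0
I,16.0,9.0
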