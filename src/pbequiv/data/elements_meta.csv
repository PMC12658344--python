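symbol,Z,atomic_mass,k_edge_keV
H,1,1.008,
C,6,12.011,
N,7,14.007,
O,8,15.999,
Al,13,26.982,1.5596
S,16,32.06,2.472
Cl,17,35.45,2.8224
Ar,18,39.948,3.2029
Sn,50,118.71,29.2
Sb,51,121.76,30.4912
Ba,56,137.327,37.4406
Gd,64,157.25,50.2391
W,74,183.84,69.525
Pb,82,207.2,88.005
Bi,83,208.98,90.526
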