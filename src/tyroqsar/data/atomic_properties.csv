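element,atomic_number,mass,sanderson_en,polarizability,vdw_volume,covalent_radius
H,1,1.008,2.592,0.667,7.238,0.31
B,5,10.811,2.275,3.030,29.648,0.84
C,6,12.011,2.746,1.760,20.580,0.76
N,7,14.007,3.194,1.100,15.599,0.71
O,8,15.999,3.654,0.802,14.710,0.66
F,9,18.998,4.000,0.557,13.305,0.57
Si,14,28.086,2.138,5.380,38.792,1.11
P,15,30.974,2.515,3.630,24.429,1.07
S,16,32.060,2.957,2.900,24.429,1.05
Cl,17,35.450,3.475,2.180,22.449,1.02
Br,35,79.904,3.219,3.050,26.522,1.20
I,53,126.904,2.778,5.350,32.515,1.39
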