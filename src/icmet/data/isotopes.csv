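# Isotopic masses (CODATA 2018 / AME2020) and representative abundances (CIAAW 2021).
# mass_shift is the nominal neutron-count offset from the lightest isotope.
element,mass_number,mass_shift,mass,abundance
H,1,0,1.00782503207,0.999885
H,2,1,2.01410177785,0.000115
C,12,0,12.0000000000,0.9893
C,13,1,13.00335483507,0.0107
N,14,0,14.00307400443,0.99636
N,15,1,15.00010889888,0.00364
O,16,0,15.99491461957,0.99757
O,17,1,16.99913175650,0.00038
O,18,2,17.99915961286,0.00205
P,31,0,30.97376199842,1.0
S,32,0,31.97207117441,0.9499
S,33,1,32.97145890982,0.0075
S,34,2,33.96786700100,0.0425
S,36,4,35.96708071000,0.0001
Na,23,0,22.98976928200,1.0
K,39,0,38.96370648640,0.932581
K,40,1,39.96399816600,0.000117
K,41,2,40.96182525790,0.067302
Cl,35,0,34.96885268200,0.7576
Cl,37,2,36.96590260200,0.2424
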