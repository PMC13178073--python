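pomolic_acid
     RDKit          2D

 34 38  0  0  0  0  0  0  0  0999 V2000
   -5.9492   -2.9342    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.1559   -1.6612    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.8617   -0.3376    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.0684    0.9354    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5692    0.8849    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7759    2.1579    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2767    2.1074    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5709    0.7838    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.1349   -0.5397    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3643   -0.4892    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6584   -1.8128    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8407   -1.8633    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.6340   -0.5903    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.1332   -0.6408    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3398   -1.9139    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.8390   -1.9644    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.3381   -2.0149    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.1315   -0.7419    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.6306   -0.7924    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    5.4257    0.5817    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.2151    2.0668    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.8517    1.0469    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.9265    0.6322    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.2207    1.9558    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.7216    2.0063    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.9282    0.7333    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.2224    2.0569    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8634   -0.4387    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.6567   -1.7117    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2653   -2.2719    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.9668   -3.1793    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -4.2750    2.2085    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.4817    3.4815    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -5.7742    2.2590    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  1  0
  7  8  1  0
  8  9  1  0
  8 10  1  0
 10 11  2  0
 11 12  1  0
 12 13  1  0
 13 14  1  0
 14 15  1  0
 14 16  1  0
 16 17  1  0
 17 18  1  0
 18 19  1  0
 18 20  1  0
 20 21  1  0
 20 22  1  0
 20 23  1  0
 23 24  1  0
 24 25  1  0
 25 26  1  0
 26 27  1  0
 10 28  1  0
 28 29  1  0
 29 30  1  0
 29 31  1  0
  5 32  1  0
 32 33  1  0
 32 34  2  0
 29  2  1  0
 28  5  1  0
 26  8  1  0
 26 13  1  0
 23 14  1  0
M  END
$$$$
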