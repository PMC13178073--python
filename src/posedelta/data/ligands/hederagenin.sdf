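hederagenin
     RDKit          2D

 34 38  0  0  0  0  0  0  0  0999 V2000
   -5.2463   -3.1981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.4244   -1.7087    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.8602   -2.1427    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.1011   -0.3700    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.2802    0.8854    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7825    0.8021    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.9615    2.0576    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4639    1.9743    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7871    0.6356    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1104   -0.7030    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6081   -0.6198    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9313   -1.9584    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5664   -2.0417    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.3873   -0.7863    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.8850   -0.8695    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0641   -2.1249    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5618   -2.2082    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.0594   -2.2914    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.8804   -1.0360    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.3781   -1.1193    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    5.2036    0.3026    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.0256    1.7920    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.6395    0.7367    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.9815    2.1971    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.7060    0.3859    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0292    1.7246    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5315    1.8078    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7106    0.5524    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0338    1.8911    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1057   -0.5365    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.9267   -1.7919    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.4592    2.1408    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.6383    3.3962    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -5.9569    2.2241    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  1  0
  7  8  1  0
  8  9  1  0
  9 10  1  0
  9 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  1  0
 14 15  1  0
 15 16  1  0
 15 17  1  0
 17 18  1  0
 18 19  1  0
 19 20  1  0
 19 21  1  0
 21 22  1  0
 21 23  1  0
 23 24  1  0
 21 25  1  0
 25 26  1  0
 26 27  1  0
 27 28  1  0
 28 29  1  0
 11 30  1  0
 30 31  1  0
  6 32  1  0
 32 33  1  0
 32 34  2  0
 31  2  1  0
 30  6  1  0
 28  9  1  0
 28 14  1  0
 25 15  1  0
M  END
$$$$
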