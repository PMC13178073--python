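caulophyllogenin
     RDKit          2D

 35 39  0  0  0  0  0  0  0  0999 V2000
   -5.0880   -3.3442    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.2897   -1.8578    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.7185   -2.3146    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.9877   -0.5301    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.1868    0.7382    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.6880    0.6788    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8871    1.9471    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1693    2.6927    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3883    1.8877    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6904    0.5600    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0076   -0.7678    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4912   -0.7084    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7933   -2.0361    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7055   -2.0955    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5064   -0.8272    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0052   -0.8866    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2044   -2.1549    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7032   -2.2143    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.2020   -2.2738    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.0029   -1.0054    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.5017   -1.0649    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    5.3049    0.3223    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.1032    1.8087    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.7337    0.7791    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.0525    2.2448    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.8061    0.3817    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.1082    1.7094    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.6093    1.7688    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8085    0.5005    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.1105    1.8283    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.9901   -0.6489    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7909   -1.9173    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.3860    2.0065    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.0457    2.7274    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -5.8848    2.0659    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  1  0
  7  8  1  0
  7  9  1  0
  9 10  1  0
 10 11  1  0
 10 12  1  0
 12 13  2  0
 13 14  1  0
 14 15  1  0
 15 16  1  0
 16 17  1  0
 16 18  1  0
 18 19  1  0
 19 20  1  0
 20 21  1  0
 20 22  1  0
 22 23  1  0
 22 24  1  0
 24 25  1  0
 22 26  1  0
 26 27  1  0
 27 28  1  0
 28 29  1  0
 29 30  1  0
 12 31  1  0
 31 32  1  0
  6 33  1  0
 33 34  1  0
 33 35  2  0
 32  2  1  0
 31  6  1  0
 29 10  1  0
 29 15  1  0
 26 16  1  0
M  END
$$$$
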