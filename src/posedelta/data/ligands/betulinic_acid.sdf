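betulinic_acid
     RDKit          2D

 33 37  0  0  0  0  0  0  0  0999 V2000
    4.9698   -3.9415    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.8262   -2.9708    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.4138   -3.4759    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.0951   -1.4951    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.4469   -0.8452    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.2466    0.6414    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7709    0.9102    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.9832    2.1867    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.4838    2.1429    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7721    0.8224    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0155    2.0990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5598   -0.4541    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8481   -1.7745    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6512   -1.8184    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4389   -0.5419    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.9383   -0.5857    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1506   -1.8623    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.6499   -1.9062    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.1493   -1.9500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.9370   -0.6735    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -7.4363   -0.7174    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -5.2253    0.6469    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.0081    2.1311    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.6492    1.1185    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7259    0.6908    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0142    2.0112    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5149    2.0551    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7272    0.7786    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0605   -0.4980    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0592   -0.4102    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.6167    2.1490    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.1124    2.0359    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.9667    3.5009    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  2  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  1  0
  7  8  1  0
  8  9  1  0
  9 10  1  0
 10 11  1  0
 10 12  1  0
 12 13  1  0
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
 22 25  1  0
 25 26  1  0
 26 27  1  0
 27 28  1  0
 28 29  1  0
 12 30  1  0
  7 31  1  0
 31 32  1  0
 31 33  2  0
 30  4  1  0
 30  7  1  0
 28 10  1  0
 28 15  1  0
 25 16  1  0
M  END
$$$$
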