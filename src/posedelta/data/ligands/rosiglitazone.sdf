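rosiglitazone
     RDKit          2D

 25 27  0  0  0  0  0  0  0  0999 V2000
   -6.5618   -2.3580    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.3266   -1.5071    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -3.9720   -2.1514    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7367   -1.3004    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3821   -1.9448    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1469   -1.0938    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2077   -1.7381    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.4430   -0.8872    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3237    0.6081    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5590    1.4590    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.9135    0.8147    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.2310    1.5318    0.0000 S   0  0  0  0  0  0  0  0  0  0  0  0
    7.3202    0.5005    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    8.7947    0.7754    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    6.6758   -0.8541    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    5.1885   -0.6599    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.1571   -1.7491    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.9691    1.2524    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2662    0.4014    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.4459   -0.0118    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.2106    0.8391    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.3299    2.3344    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.6845    2.9787    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.9197    2.1277    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.8004    0.6325    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  2  0
  7  8  1  0
  8  9  2  0
  9 10  1  0
 10 11  1  0
 11 12  1  0
 12 13  1  0
 13 14  2  0
 13 15  1  0
 15 16  1  0
 16 17  2  0
  9 18  1  0
 18 19  2  0
  2 20  1  0
 20 21  2  0
 21 22  1  0
 22 23  2  0
 23 24  1  0
 24 25  2  0
 19  6  1  0
 25 20  1  0
 16 11  1  0
M  END
$$$$
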