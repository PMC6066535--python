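BER-like tetracyclic cation (synthetic template)
     RDKit          3D

 25 29  0  0  0  0  0  0  0  0999 V2000
    6.2290    1.0112    2.0920 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.6892    0.3702    0.9387 O   0  0  0  0  0  0  0  0  0  0  0  0
    4.3217    0.4170    0.9017 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5919    1.0439    1.9185 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2029    1.0976    1.8861 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5149    0.5207    0.8266 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.1276    0.5694    0.7921 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5602   -0.0148   -0.2718 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.1395   -0.6155   -1.2641 N   0  0  0  0  0  4  0  0  0  0  0  0
    1.4835   -0.6749   -1.2525 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2221   -0.1155   -0.2079 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.6340   -0.1714   -0.1756 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.1813   -0.8231   -1.2542 O   0  0  0  0  0  0  0  0  0  0  0  0
    5.6007   -0.9153   -1.2412 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5066   -1.1549   -2.4706 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7876   -1.8731   -2.0988 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6392   -0.9623   -1.2736 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.0305   -1.0412   -1.3897 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.7823   -0.2033   -0.5950 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.1980    0.6743    0.2827 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8271    0.7668    0.4157 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0174   -0.0602   -0.3763 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.1102    1.4063    0.9696 O   0  0  0  0  0  0  0  0  0  0  0  0
   -6.3429    0.8834    0.4293 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.1364   -0.1349   -0.5724 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  2  0
  8  9  1  0
  9 10  2  0
 10 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  1  0
  9 15  1  0
 15 16  1  0
 16 17  1  0
 17 18  2  0
 18 19  1  0
 19 20  2  0
 20 21  1  0
 21 22  2  0
 20 23  1  0
 23 24  1  0
 24 25  1  0
 12  3  1  0
 22 17  1  0
 11  6  1  0
 25 19  1  0
 22  8  1  0
M  CHG  1   9   1
M  END
$$$$
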