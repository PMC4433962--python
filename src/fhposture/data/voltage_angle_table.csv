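degree,flex,x,y,z
-60,1065,917,943,950
-50,1117,996,998,996
-40,1187,1119,1113,1113
-30,1273,1213,1216,1204
-20,1345,1316,1312,1335
-10,1443,1453,1461,1486
0,1500,1590,1622,1634
10,1655,1740,1768,1778
20,1720,1841,1911,1883
30,1811,1966,2034,1995
40,1903,2098,2141,2137
50,1998,2196,2261,2257
60,2112,2290,2320,2324
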