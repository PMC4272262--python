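# Viscosity (cP) of aqueous sucrose solutions vs temperature (C, rows)
# and sucrose concentration (% w/w, columns); smooth handbook-anchored
# parameterization (water at 20 C = 1.002 cP; 20% = 1.945 cP at 20 C).
T_C,w0,w5,w10,w15,w20,w25,w30,w35,w40
0,1.7769,2.0322,2.4054,2.9463,3.7346,4.8989,6.6503,9.3426,13.5824
5,1.5125,1.7237,2.0309,2.4742,3.1163,4.0583,5.4642,7.6067,10.9485
10,1.3042,1.4810,1.7372,2.1048,2.6343,3.4057,4.5482,6.2742,8.9405
15,1.1375,1.2870,1.5028,1.8110,2.2522,2.8907,3.8289,5.2340,7.3839
20,1.0020,1.1296,1.3131,1.5738,1.9449,2.4781,3.2557,4.4101,6.1595
25,0.8905,1.0003,1.1575,1.3798,1.6943,2.1433,2.7928,3.7488,5.1837
30,0.7976,0.8927,1.0284,1.2193,1.4877,1.8683,2.4146,3.2118,4.3968
35,0.7194,0.8023,0.9201,1.0850,1.3155,1.6400,2.1023,2.7710,3.7555
40,0.6530,0.7256,0.8284,0.9715,1.1705,1.4487,1.8419,2.4058,3.2280
45,0.5960,0.6600,0.7501,0.8749,1.0474,1.2869,1.6229,2.1005,2.7903
50,0.5469,0.6034,0.6826,0.7919,0.9420,1.1491,1.4372,1.8434,2.4243
55,0.5041,0.5541,0.6241,0.7201,0.8512,1.0307,1.2787,1.6252,2.1161
60,0.4666,0.5111,0.5730,0.6576,0.7723,0.9285,1.1425,1.4389,1.8548
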