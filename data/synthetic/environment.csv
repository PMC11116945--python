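sample_id,SM,ST,pH,STC,STN,STP
Heihe_farmland_r1_2019,22.0885,16.8122,6.2495,16.9655,2.0203,0.6373
Heihe_farmland_r1_2021,24.0346,14.1917,6.2967,19.1029,1.7173,0.6532
Heihe_farmland_r2_2019,23.4938,14.8151,6.3507,20.9837,2.0144,0.6174
Heihe_farmland_r2_2021,23.7352,14.8158,6.4091,22.0289,1.9353,0.7229
Heihe_farmland_r3_2019,23.7628,15.0557,6.6495,17.0531,1.629,0.5902
Heihe_farmland_r3_2021,24.6358,13.5735,6.0735,18.5813,1.8454,0.718
Heihe_grassland_r1_2019,21.1286,15.1007,6.7335,19.4383,2.1018,0.6514
Heihe_grassland_r1_2021,25.8488,14.4216,6.1398,19.9455,1.9678,0.5996
Heihe_grassland_r2_2019,20.0822,13.2234,6.5468,19.791,1.9422,0.6023
Heihe_grassland_r2_2021,28.0331,13.7011,6.1691,17.7387,1.9616,0.6566
Heihe_grassland_r3_2019,26.8677,14.9609,6.0799,19.3888,2.0464,0.68
Heihe_grassland_r3_2021,24.7134,15.6926,6.1907,20.3376,1.7112,0.5586
Heihe_woodland_r1_2019,25.6565,14.7114,6.1426,18.3456,1.89,0.7235
Heihe_woodland_r1_2021,28.8493,14.316,6.3679,19.8208,1.6688,0.5749
Heihe_woodland_r2_2019,24.7825,15.8255,6.4599,21.4833,2.0054,0.6277
Heihe_woodland_r2_2021,25.6659,14.0347,6.7169,20.4615,2.0388,0.5575
Heihe_woodland_r3_2019,26.8371,14.4733,6.2849,20.1488,1.9707,0.6133
Heihe_woodland_r3_2021,23.1394,14.6883,6.1267,20.3094,1.7275,0.6584
Harbin_farmland_r1_2019,30.6978,19.8508,6.688,13.6274,1.4605,0.6667
Harbin_farmland_r1_2021,27.8293,18.3026,6.8434,15.8741,1.2334,0.501
Harbin_farmland_r2_2019,22.9704,18.8527,6.8184,16.2813,1.8025,0.5785
Harbin_farmland_r2_2021,25.4773,19.2775,6.5414,14.156,1.4672,0.6258
Harbin_farmland_r3_2019,27.7623,18.2885,7.1927,15.1005,1.4013,0.5771
Harbin_farmland_r3_2021,23.5285,18.7865,6.9258,16.1246,1.4864,0.5922
Harbin_grassland_r1_2019,25.0597,17.1266,7.0467,14.4868,1.2282,0.6258
Harbin_grassland_r1_2021,23.2199,18.5977,7.0052,15.2217,1.4892,0.555
Harbin_grassland_r2_2019,23.9462,18.5827,6.5259,13.3835,1.3611,0.4946
Harbin_grassland_r2_2021,24.815,17.7728,6.7977,13.2798,1.4515,0.5708
Harbin_grassland_r3_2019,25.9143,15.7495,6.7465,15.5626,1.1497,0.4701
Harbin_grassland_r3_2021,23.1781,16.2171,7.1794,16.4924,1.4982,0.6261
Harbin_woodland_r1_2019,28.3581,18.688,6.9975,13.7831,1.3484,0.5194
Harbin_woodland_r1_2021,23.3872,18.7193,7.1791,13.9506,1.2642,0.5303
Harbin_woodland_r2_2019,25.1449,19.2238,6.8831,13.0743,1.3113,0.5811
Harbin_woodland_r2_2021,26.7837,19.5342,7.0065,15.7796,1.6737,0.5781
Harbin_woodland_r3_2019,27.7403,19.6009,6.8119,15.0257,1.4428,0.5249
Harbin_woodland_r3_2021,23.5377,19.3847,6.7504,14.7774,1.4759,0.5584
Lishu_farmland_r1_2019,26.404,16.8651,7.4881,10.9443,1.3559,0.4181
Lishu_farmland_r1_2021,26.8986,17.8018,7.0739,12.6709,1.051,0.4659
Lishu_farmland_r2_2019,27.8927,19.417,7.483,11.4962,1.0924,0.6329
Lishu_farmland_r2_2021,27.4623,18.6191,6.9844,12.819,1.3345,0.6287
Lishu_farmland_r3_2019,31.8186,18.1167,7.0515,11.086,1.2018,0.5416
Lishu_farmland_r3_2021,26.8152,18.9912,7.4468,11.2581,1.277,0.4112
Lishu_grassland_r1_2019,28.245,17.4616,6.9388,11.1566,1.3749,0.4798
Lishu_grassland_r1_2021,27.3639,19.9924,7.0088,10.4848,1.452,0.5541
Lishu_grassland_r2_2019,28.8381,18.9748,7.3102,10.3248,1.2997,0.4745
Lishu_grassland_r2_2021,28.1695,18.2163,7.2152,12.7078,1.2397,0.4303
Lishu_grassland_r3_2019,28.1295,19.7357,6.9793,9.3492,1.054,0.3999
Lishu_grassland_r3_2021,25.3746,18.5985,7.0228,13.1979,1.1035,0.5102
Lishu_woodland_r1_2019,23.8719,20.7954,7.1831,10.9993,0.9669,0.508
Lishu_woodland_r1_2021,23.2412,18.357,7.439,10.6447,1.1792,0.492
Lishu_woodland_r2_2019,27.6569,18.3573,7.2024,11.5307,1.1143,0.5611
Lishu_woodland_r2_2021,27.2585,18.2322,7.0754,13.9961,1.2197,0.5728
Lishu_woodland_r3_2019,23.8324,18.302,7.2297,13.5635,1.106,0.6125
Lishu_woodland_r3_2021,27.9226,17.7235,7.6147,11.3704,1.2463,0.4867
Shenyang_farmland_r1_2019,29.6749,22.0646,7.2512,6.9412,0.7453,0.4588
Shenyang_farmland_r1_2021,32.1606,20.0447,7.7666,11.3727,0.8681,0.4675
Shenyang_farmland_r2_2019,29.4233,22.5528,7.3595,8.9643,0.6846,0.4597
Shenyang_farmland_r2_2021,33.5063,21.5742,7.4901,7.3545,0.7487,0.5543
Shenyang_farmland_r3_2019,29.9504,20.7075,7.3901,10.1751,0.673,0.4797
Shenyang_farmland_r3_2021,29.7103,21.611,7.7373,10.0804,0.8745,0.4466
Shenyang_grassland_r1_2019,28.482,21.3064,7.6094,9.1382,0.9313,0.4977
Shenyang_grassland_r1_2021,31.4203,21.925,7.4927,10.7418,0.799,0.4609
Shenyang_grassland_r2_2019,28.2472,19.589,7.2439,9.961,0.7729,0.4348
Shenyang_grassland_r2_2021,31.019,21.4587,7.7043,9.1153,0.5706,0.4556
Shenyang_grassland_r3_2019,32.4499,21.7624,7.1994,9.4861,0.8989,0.4538
Shenyang_grassland_r3_2021,29.8743,21.7862,7.632,10.4052,1.0505,0.5045
Shenyang_woodland_r1_2019,31.2606,20.6526,7.4928,8.8967,0.8372,0.5276
Shenyang_woodland_r1_2021,29.7676,19.9804,7.4831,8.4227,0.9051,0.4071
Shenyang_woodland_r2_2019,35.1619,21.9999,7.3632,7.9752,0.4927,0.4498
Shenyang_woodland_r2_2021,28.6427,20.2564,7.7163,11.0157,0.8949,0.3315
Shenyang_woodland_r3_2019,29.1224,20.5394,7.4561,9.1654,1.1727,0.3994
Shenyang_woodland_r3_2021,29.9021,21.2095,7.683,8.4497,0.5602,0.496
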