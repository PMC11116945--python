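sample_id,Genus01,Genus02,Genus03,Genus04,Genus05,Genus06,Genus07,Genus08,Genus09,Genus10,Genus11,Genus12,Genus13,Genus14,Genus15,Genus16,Genus17,Genus18,Genus19,Genus20,Genus21,Genus22,Genus23,Genus24,Genus25,Genus26,Genus27,Genus28,Genus29,Genus30,Genus31,Genus32
Heihe_farmland_r1_2019,0,4,4,0,0,2,0,4,7,0,0,4,1,2,0,4,0,1,0,0,0,0,15,0,37,0,2,7,4,1,0,1
Heihe_farmland_r1_2021,0,0,0,0,0,2,4,0,6,0,0,0,1,0,0,10,0,3,0,3,0,0,0,6,25,0,0,36,1,0,0,3
Heihe_farmland_r2_2019,0,2,0,1,0,0,0,4,8,0,0,4,2,0,4,29,0,1,0,0,0,0,9,0,0,0,1,27,1,6,0,1
Heihe_farmland_r2_2021,0,0,1,3,0,0,14,3,0,2,0,2,2,0,0,11,0,4,0,0,0,0,13,0,19,0,4,8,1,0,10,3
Heihe_farmland_r3_2019,0,2,1,0,11,2,6,4,6,2,0,3,0,0,0,13,0,0,0,1,0,0,23,1,16,0,0,4,2,0,0,3
Heihe_farmland_r3_2021,0,0,1,1,0,4,11,5,7,0,0,5,0,0,0,0,0,0,0,5,0,0,20,2,0,0,0,25,1,5,0,8
Heihe_grassland_r1_2019,0,6,2,0,9,2,16,2,0,0,0,2,0,0,3,0,0,2,0,0,0,0,0,0,46,0,0,7,1,0,0,2
Heihe_grassland_r1_2021,0,0,2,0,18,1,0,6,0,0,0,6,0,0,9,17,0,0,0,0,0,0,27,4,0,0,0,0,4,1,0,5
Heihe_grassland_r2_2019,0,0,3,0,0,4,41,16,0,0,0,7,1,0,0,0,15,2,0,0,0,0,0,0,0,0,0,0,0,10,0,1
Heihe_grassland_r2_2021,1,3,1,0,11,2,27,2,6,0,0,4,0,0,12,9,0,1,0,1,0,0,13,0,0,0,5,0,1,1,0,0
Heihe_grassland_r3_2019,0,0,0,0,0,0,0,3,13,0,0,5,3,0,0,49,13,3,0,0,0,0,0,0,0,0,1,0,4,3,0,3
Heihe_grassland_r3_2021,0,0,2,0,0,0,4,2,0,0,0,1,0,0,3,7,7,3,0,0,0,0,28,0,20,0,0,13,5,0,0,5
Heihe_woodland_r1_2019,0,5,2,0,0,1,16,1,4,0,0,1,0,0,0,29,3,0,0,5,0,0,15,0,13,0,1,0,0,0,0,4
Heihe_woodland_r1_2021,0,0,1,0,0,2,6,0,6,0,0,2,2,0,0,8,5,1,0,1,0,0,11,2,39,0,2,0,0,6,3,3
Heihe_woodland_r2_2019,0,0,1,1,0,3,11,4,5,0,0,2,0,0,0,8,0,2,3,0,0,0,25,0,17,0,1,0,0,0,16,1
Heihe_woodland_r2_2021,0,0,2,0,0,2,0,0,0,0,0,0,2,0,0,16,0,0,0,5,0,0,31,4,30,0,4,0,0,0,0,4
Heihe_woodland_r3_2019,0,1,1,0,0,4,16,0,3,0,0,0,1,0,7,17,0,1,0,2,0,0,13,3,0,0,2,17,5,2,0,5
Heihe_woodland_r3_2021,0,2,3,0,7,3,5,2,0,0,0,2,2,0,0,15,0,1,0,5,0,0,29,0,8,0,2,13,1,0,0,0
Harbin_farmland_r1_2019,4,0,2,1,6,0,10,2,4,2,1,0,1,1,2,0,0,1,1,2,4,0,22,0,25,0,0,6,1,1,0,1
Harbin_farmland_r1_2021,0,1,0,0,7,0,4,2,5,3,0,0,1,2,0,14,1,0,2,0,2,17,8,2,15,2,0,8,0,2,0,2
Harbin_farmland_r2_2019,7,0,2,2,13,0,0,3,0,0,0,0,0,1,0,8,2,0,1,3,2,0,8,1,7,0,0,15,0,6,14,5
Harbin_farmland_r2_2021,8,5,0,1,9,0,18,4,15,4,0,0,2,3,0,0,4,0,1,3,0,0,0,5,0,0,0,8,3,3,0,4
Harbin_farmland_r3_2019,0,2,1,0,6,0,5,0,8,0,0,0,2,0,1,18,0,0,2,4,5,0,7,3,24,0,0,0,0,0,10,2
Harbin_farmland_r3_2021,4,0,0,2,21,0,12,2,0,3,1,0,3,1,2,0,2,0,0,0,2,15,0,1,13,0,0,7,2,0,6,1
Harbin_grassland_r1_2019,2,5,0,0,14,0,13,4,3,0,2,0,0,4,1,0,5,2,1,8,4,0,21,3,0,0,0,0,2,1,5,0
Harbin_grassland_r1_2021,2,1,1,0,17,0,0,0,0,0,1,0,0,0,4,14,4,0,2,3,3,0,18,2,10,1,0,6,2,0,7,2
Harbin_grassland_r2_2019,6,3,1,2,11,0,0,6,0,1,1,0,0,1,7,0,0,0,1,4,4,23,9,2,13,2,0,0,2,1,0,0
Harbin_grassland_r2_2021,1,1,1,1,10,0,12,6,0,0,0,0,1,1,1,0,3,0,3,7,4,0,0,0,15,0,0,18,1,3,11,0
Harbin_grassland_r3_2019,2,1,1,1,8,0,12,3,4,0,0,0,2,0,4,0,0,0,4,2,3,0,24,3,9,0,0,10,3,3,0,1
Harbin_grassland_r3_2021,5,1,1,1,11,0,6,3,0,2,0,0,0,0,0,12,3,0,2,2,2,0,19,3,7,0,4,11,2,3,0,0
Harbin_woodland_r1_2019,2,1,1,0,6,0,5,2,1,1,2,0,1,0,0,7,0,0,3,2,0,46,5,0,4,1,2,0,2,1,5,0
Harbin_woodland_r1_2021,2,0,0,3,0,0,8,2,5,0,2,0,1,0,0,0,0,2,2,5,4,0,19,0,19,4,1,0,3,2,11,5
Harbin_woodland_r2_2019,0,1,1,2,7,0,14,2,0,0,2,0,0,1,6,0,2,0,1,3,4,14,0,0,30,3,1,0,2,3,0,1
Harbin_woodland_r2_2021,6,3,3,0,0,0,0,0,19,0,1,0,2,0,0,0,2,0,1,1,4,29,16,0,0,0,4,0,2,2,5,0
Harbin_woodland_r3_2019,0,4,0,4,10,0,0,0,0,0,1,0,2,0,1,0,0,0,3,5,1,0,0,0,42,0,0,12,1,0,11,3
Harbin_woodland_r3_2021,0,4,2,0,0,0,0,0,2,2,0,0,1,0,3,8,3,0,2,5,6,25,14,0,16,0,0,0,1,2,2,2
Lishu_farmland_r1_2019,4,1,1,2,4,0,11,2,0,1,2,0,0,1,0,0,0,0,1,8,4,29,0,0,0,2,1,11,2,1,12,0
Lishu_farmland_r1_2021,7,3,0,2,0,0,0,0,6,6,0,0,2,1,0,0,0,0,0,9,0,27,16,0,0,1,0,14,1,5,0,0
Lishu_farmland_r2_2019,3,0,0,1,0,0,0,0,4,1,1,0,1,1,5,6,2,0,1,0,0,54,5,1,6,2,0,5,0,1,0,0
Lishu_farmland_r2_2021,3,0,0,0,16,0,0,1,12,4,0,0,0,3,0,0,0,0,2,0,7,0,0,0,27,1,0,20,1,3,0,0
Lishu_farmland_r3_2019,0,0,0,2,4,0,6,1,8,2,0,0,4,1,0,0,0,0,2,0,2,10,12,0,21,1,0,8,2,0,14,0
Lishu_farmland_r3_2021,3,4,0,1,4,0,0,2,2,1,1,0,1,1,0,0,1,0,1,1,2,33,0,0,10,2,0,15,2,2,11,0
Lishu_grassland_r1_2019,4,7,0,0,5,0,0,4,5,2,3,0,0,1,9,0,0,0,2,4,0,0,16,0,20,0,0,0,1,2,15,0
Lishu_grassland_r1_2021,3,0,0,2,0,0,10,3,8,0,1,0,3,3,5,0,0,0,2,8,5,0,17,11,0,2,0,11,1,5,0,0
Lishu_grassland_r2_2019,3,0,0,0,7,0,0,0,0,1,1,0,0,1,7,0,0,3,0,5,3,28,0,0,0,0,0,14,1,1,25,0
Lishu_grassland_r2_2021,3,0,0,0,0,0,2,2,7,0,1,0,1,0,0,8,0,2,2,0,3,27,0,0,29,1,0,0,1,3,8,0
Lishu_grassland_r3_2019,7,1,0,1,6,0,0,2,0,2,0,0,3,0,6,0,4,1,1,7,0,20,5,0,12,2,1,6,0,4,9,0
Lishu_grassland_r3_2021,2,0,0,2,11,0,0,0,0,2,1,0,1,1,3,0,0,0,0,3,0,26,31,0,4,1,0,9,1,2,0,0
Lishu_woodland_r1_2019,4,0,0,2,0,0,10,0,0,5,0,0,2,0,5,0,0,2,4,2,3,26,0,0,17,0,3,15,0,0,0,0
Lishu_woodland_r1_2021,6,1,0,1,0,0,0,0,0,0,5,0,1,0,0,0,0,0,1,5,0,53,0,0,14,0,1,0,2,0,10,0
Lishu_woodland_r2_2019,0,1,0,1,0,0,0,0,0,1,1,0,1,0,5,8,3,1,0,1,0,39,0,0,18,0,1,0,1,1,17,0
Lishu_woodland_r2_2021,5,1,0,0,0,0,0,4,0,1,2,0,2,0,1,8,0,0,0,4,1,18,0,0,31,1,0,10,0,0,11,0
Lishu_woodland_r3_2019,0,0,0,2,9,0,0,0,23,3,3,0,0,3,4,0,5,0,1,13,2,0,0,5,0,1,4,0,1,4,17,0
Lishu_woodland_r3_2021,0,1,0,0,0,0,0,0,0,1,1,0,1,1,2,15,4,0,0,3,5,44,0,0,19,0,0,3,0,0,0,0
Shenyang_farmland_r1_2019,0,0,0,2,0,0,0,0,9,2,2,0,0,3,15,0,0,0,0,3,3,0,32,0,0,0,0,0,0,4,25,0
Shenyang_farmland_r1_2021,0,2,0,2,0,0,6,2,2,1,0,0,1,1,0,0,0,0,2,3,0,19,11,0,23,0,0,14,0,4,7,0
Shenyang_farmland_r2_2019,0,0,0,1,5,0,0,5,6,4,2,0,1,3,0,0,0,0,0,0,0,0,18,0,24,0,0,21,2,0,8,0
Shenyang_farmland_r2_2021,5,0,0,4,10,0,0,0,18,2,4,0,1,2,0,0,0,0,2,0,0,0,17,0,18,0,0,6,2,0,9,0
Shenyang_farmland_r3_2019,5,0,0,0,8,0,0,0,0,2,0,0,0,2,0,0,0,0,4,0,3,38,0,0,0,0,2,15,0,2,19,0
Shenyang_farmland_r3_2021,4,2,0,0,9,0,0,0,6,2,0,0,1,3,0,0,0,0,2,0,3,5,15,0,25,1,0,6,3,0,13,0
Shenyang_grassland_r1_2019,5,2,0,0,43,0,0,0,0,0,2,0,0,0,0,0,0,0,2,0,0,0,0,0,0,0,0,0,5,0,41,0
Shenyang_grassland_r1_2021,2,2,0,3,0,0,2,6,5,2,2,0,0,1,0,0,7,0,0,2,0,18,0,0,13,2,0,0,5,1,27,0
Shenyang_grassland_r2_2019,11,12,0,0,0,0,16,0,0,0,3,0,0,2,0,0,0,0,6,10,0,27,0,0,0,0,0,0,6,7,0,0
Shenyang_grassland_r2_2021,8,1,0,1,0,0,0,7,0,0,2,0,0,1,17,0,0,0,2,0,0,0,21,0,20,2,0,6,1,0,11,0
Shenyang_grassland_r3_2019,1,1,0,0,0,0,0,0,0,0,2,0,0,2,0,0,0,0,2,0,0,46,16,0,0,2,0,5,1,4,18,0
Shenyang_grassland_r3_2021,4,6,0,4,0,0,0,4,0,0,2,0,1,1,7,0,0,0,3,9,0,0,29,0,0,1,0,13,1,0,15,0
Shenyang_woodland_r1_2019,0,1,0,1,0,0,0,0,0,0,1,0,0,1,0,0,0,0,1,0,0,27,0,0,38,0,0,10,0,0,20,0
Shenyang_woodland_r1_2021,0,2,0,5,0,0,0,0,22,0,6,0,0,0,0,0,0,0,7,11,10,0,0,0,0,4,0,0,0,0,33,0
Shenyang_woodland_r2_2019,0,2,0,1,0,0,0,0,0,2,2,0,1,0,1,0,0,0,0,7,0,63,11,0,0,0,0,0,1,0,9,0
Shenyang_woodland_r2_2021,6,0,0,2,0,0,0,0,9,3,5,0,2,1,4,0,0,0,0,0,0,25,0,0,0,2,0,25,0,0,16,0
Shenyang_woodland_r3_2019,4,2,0,2,0,0,0,0,6,0,1,0,1,1,0,0,0,0,2,6,0,53,0,0,0,0,0,0,1,0,21,0
Shenyang_woodland_r3_2021,0,4,0,0,0,0,0,0,0,2,4,0,2,5,0,0,0,0,2,12,0,53,0,0,0,3,0,0,0,0,13,0
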