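sample_id,site,land_cover,year,replicate,longitude,latitude
Heihe_farmland_r1_2019,Heihe,farmland,2019,1,127.43826841303553,50.25637751159641
Heihe_farmland_r1_2021,Heihe,farmland,2021,1,127.43826841303553,50.25637751159641
Heihe_farmland_r2_2019,Heihe,farmland,2019,2,127.43332513409561,50.26392138400546
Heihe_farmland_r2_2021,Heihe,farmland,2021,2,127.43332513409561,50.26392138400546
Heihe_farmland_r3_2019,Heihe,farmland,2019,3,127.46767489081125,50.2507880787026
Heihe_farmland_r3_2021,Heihe,farmland,2021,3,127.46767489081125,50.2507880787026
Heihe_grassland_r1_2019,Heihe,grassland,2019,1,127.45374863045133,50.234191445544944
Heihe_grassland_r1_2021,Heihe,grassland,2021,1,127.45374863045133,50.234191445544944
Heihe_grassland_r2_2019,Heihe,grassland,2019,2,127.45585332466646,50.232582726574
Heihe_grassland_r2_2021,Heihe,grassland,2021,2,127.45585332466646,50.232582726574
Heihe_grassland_r3_2019,Heihe,grassland,2019,3,127.45247575239534,50.24167289190617
Heihe_grassland_r3_2021,Heihe,grassland,2021,3,127.45247575239534,50.24167289190617
Heihe_woodland_r1_2019,Heihe,woodland,2019,1,127.4365654769872,50.233321325860025
Heihe_woodland_r1_2021,Heihe,woodland,2021,1,127.4365654769872,50.233321325860025
Heihe_woodland_r2_2019,Heihe,woodland,2019,2,127.47165818370829,50.232328810463386
Heihe_woodland_r2_2021,Heihe,woodland,2021,2,127.47165818370829,50.232328810463386
Heihe_woodland_r3_2019,Heihe,woodland,2019,3,127.4580730204399,50.264939720219814
Heihe_woodland_r3_2021,Heihe,woodland,2021,3,127.4580730204399,50.264939720219814
Harbin_farmland_r1_2019,Harbin,farmland,2019,1,126.55841904378501,45.655952202765945
Harbin_farmland_r1_2021,Harbin,farmland,2021,1,126.55841904378501,45.655952202765945
Harbin_farmland_r2_2019,Harbin,farmland,2019,2,126.56909463937303,45.66542622043134
Harbin_farmland_r2_2021,Harbin,farmland,2021,2,126.56909463937303,45.66542622043134
Harbin_farmland_r3_2019,Harbin,farmland,2019,3,126.59678623116163,45.67501273941257
Harbin_farmland_r3_2021,Harbin,farmland,2021,3,126.59678623116163,45.67501273941257
Harbin_grassland_r1_2019,Harbin,grassland,2019,1,126.57245854867806,45.6755758264147
Harbin_grassland_r1_2021,Harbin,grassland,2021,1,126.57245854867806,45.6755758264147
Harbin_grassland_r2_2019,Harbin,grassland,2019,2,126.58924694152638,45.658357517604955
Harbin_grassland_r2_2021,Harbin,grassland,2021,2,126.58924694152638,45.658357517604955
Harbin_grassland_r3_2019,Harbin,grassland,2019,3,126.56587078800362,45.66539510173254
Harbin_grassland_r3_2021,Harbin,grassland,2021,3,126.56587078800362,45.66539510173254
Harbin_woodland_r1_2019,Harbin,woodland,2019,1,126.57497510219773,45.678726149917956
Harbin_woodland_r1_2021,Harbin,woodland,2021,1,126.57497510219773,45.678726149917956
Harbin_woodland_r2_2019,Harbin,woodland,2019,2,126.57486939001683,45.65519012085224
Harbin_woodland_r2_2021,Harbin,woodland,2021,2,126.57486939001683,45.65519012085224
Harbin_woodland_r3_2019,Harbin,woodland,2019,3,126.58862217178154,45.674100760388164
Harbin_woodland_r3_2021,Harbin,woodland,2021,3,126.58862217178154,45.674100760388164
Lishu_farmland_r1_2019,Lishu,farmland,2019,1,124.62123370255794,43.35542087570192
Lishu_farmland_r1_2021,Lishu,farmland,2021,1,124.62123370255794,43.35542087570192
Lishu_farmland_r2_2019,Lishu,farmland,2019,2,124.608823659992,43.36203335495726
Lishu_farmland_r2_2021,Lishu,farmland,2021,2,124.608823659992,43.36203335495726
Lishu_farmland_r3_2019,Lishu,farmland,2019,3,124.61159843864527,43.35655033217921
Lishu_farmland_r3_2021,Lishu,farmland,2021,3,124.61159843864527,43.35655033217921
Lishu_grassland_r1_2019,Lishu,grassland,2019,1,124.62759204959391,43.35135759423258
Lishu_grassland_r1_2021,Lishu,grassland,2021,1,124.62759204959391,43.35135759423258
Lishu_grassland_r2_2019,Lishu,grassland,2019,2,124.61371478966772,43.32934791688903
Lishu_grassland_r2_2021,Lishu,grassland,2021,2,124.61371478966772,43.32934791688903
Lishu_grassland_r3_2019,Lishu,grassland,2019,3,124.60485795671882,43.321661441042586
Lishu_grassland_r3_2021,Lishu,grassland,2021,3,124.60485795671882,43.321661441042586
Lishu_woodland_r1_2019,Lishu,woodland,2019,1,124.5989730423806,43.35375309716528
Lishu_woodland_r1_2021,Lishu,woodland,2021,1,124.5989730423806,43.35375309716528
Lishu_woodland_r2_2019,Lishu,woodland,2019,2,124.62371559656383,43.339007763642556
Lishu_woodland_r2_2021,Lishu,woodland,2021,2,124.62371559656383,43.339007763642556
Lishu_woodland_r3_2019,Lishu,woodland,2019,3,124.62314066830965,43.366744791927744
Lishu_woodland_r3_2021,Lishu,woodland,2021,3,124.62314066830965,43.366744791927744
Shenyang_farmland_r1_2019,Shenyang,farmland,2019,1,123.55146852905939,40.77698803793719
Shenyang_farmland_r1_2021,Shenyang,farmland,2021,1,123.55146852905939,40.77698803793719
Shenyang_farmland_r2_2019,Shenyang,farmland,2019,2,123.55025471530706,40.797070339719035
Shenyang_farmland_r2_2021,Shenyang,farmland,2021,2,123.55025471530706,40.797070339719035
Shenyang_farmland_r3_2019,Shenyang,farmland,2019,3,123.53485747731968,40.79744514961394
Shenyang_farmland_r3_2021,Shenyang,farmland,2021,3,123.53485747731968,40.79744514961394
Shenyang_grassland_r1_2019,Shenyang,grassland,2019,1,123.57372395563722,40.8027075608058
Shenyang_grassland_r1_2021,Shenyang,grassland,2021,1,123.57372395563722,40.8027075608058
Shenyang_grassland_r2_2019,Shenyang,grassland,2019,2,123.54814628090566,40.79248672414696
Shenyang_grassland_r2_2021,Shenyang,grassland,2021,2,123.54814628090566,40.79248672414696
Shenyang_grassland_r3_2019,Shenyang,grassland,2019,3,123.5501854855974,40.788376179916575
Shenyang_grassland_r3_2021,Shenyang,grassland,2021,3,123.5501854855974,40.788376179916575
Shenyang_woodland_r1_2019,Shenyang,woodland,2019,1,123.54427772546968,40.80298348704308
Shenyang_woodland_r1_2021,Shenyang,woodland,2021,1,123.54427772546968,40.80298348704308
Shenyang_woodland_r2_2019,Shenyang,woodland,2019,2,123.54974018259989,40.790272159351616
Shenyang_woodland_r2_2021,Shenyang,woodland,2021,2,123.54974018259989,40.790272159351616
Shenyang_woodland_r3_2019,Shenyang,woodland,2019,3,123.54853439415992,40.778822060818115
Shenyang_woodland_r3_2021,Shenyang,woodland,2021,3,123.54853439415992,40.778822060818115
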