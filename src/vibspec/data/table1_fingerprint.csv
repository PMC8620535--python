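exp_position,exp_label,gatti_position,gatti_intensity,tzvp_position,tzvp_intensity,diff_gatti,diff_tzvp,assignment
1664,vs,1692,82.5,1665,100.0,-28,-1,"deltaring, nuC=O"
1652,vs,1679,100.0,,,-27,,"deltaring, nuC=O"
1623,m,1645,33.3,1632,26.5,-22,-9,"deltaring (nuCC), nuC=O"
1590,s,1609,49.1,1601,89.7,-19,-11,"deltaring, deltaCH"
1461,w,1492,1.8,1484,11.8,-31,-23,"deltaring, deltaCH, delta_asCH3"
1440,w,1472,7.0,1471,5.9,-32,-31,delta_asCH3
1425,w,1459,5.3,1413,8.8,-34,12,delta_asCH3
1380,m,1409,8.8,1372,17.6,-29,8,delta_sCH3
1353,m,1368,12.3,1351,8.8,-15,2,"deltaring, deltaCH"
1329,m,1356,3.5,,,-27,,"deltaring, deltaCH"
1299,s,1310,66.7,1314,41.2,-11,-15,"deltaring, deltaCH"
1264,m,1274,50.9,1281,44.1,-10,-17,"deltaring, deltaCH"
1238,w,1241,5.3,1251,4.4,-3,-13,"deltaring, deltaCH"
1169,w,1187,1.8,1190,4.4,-18,-21,"deltaring, deltaCH"
1156,m,1177,1.8,1177,7.4,-21,-21,"deltaring, deltaCH"
1107,vw,1126,14.0,1130,2.9,-19,-23,"deltaring, deltaCH"
1030,vw,1055,3.5,1065,1.5,-25,-35,"gammaCH, rhoCH3"
1019,w,1029,3.5,1040,7.4,-10,-21,"gammaCH, rhoCH3"
940,w,950,5.3,961,5.9,-10,-21,deltaring
900,w,930,10.5,935,5.9,-30,-35,"gammaring, gammaCH, rhoCH3"
883,w,919,7.0,,,-36,,"gammaring, gammaCH, rhoCH3"
791,w,807,12.3,809,8.8,-16,-18,"gammaring, gammaCH"
777,s,798,12.3,795,5.9,-21,-18,"gammaring, gammaCH"
720,w,722,3.5,727,1.5,-2,-7,deltaring
690,m,703,10.5,694,14.7,-13,-4,gammaring
664,m,685,5.3,676,8.8,-21,-12,gammaring
650,vw,657,1.8,665,2.9,-7,-15,deltaring
642,vw,651,1.8,654,1.5,-9,-12,deltaring
514,w,524,3.5,523,1.5,-10,-9,deltaring
459,w,464,3.5,468,1.5,-5,-9,deltaring
405,w,412,5.3,414,4.4,-7,-9,deltaring
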