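exp_positions,calc_positions,calc_intensity,difference,assignment
2781,2780,1.1,1,"delta_asymCH3 + (deltaring, deltaCH)"
2759,2750,1.9,9,"(deltaring, deltaCH) + deltaCH"
2747,2743,3.6,4,2delta_symCH3
2727,2737,1.6,-10,"(deltaring, deltaCH) + deltaCH"
2711,2723,1.6,-12,"delta_symCH3 + (deltaring, deltaCH)"
2702,2713,2.1,-11,"(deltaring, deltaCH) + deltaCH"
2680,2687,4.4,-7,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2655,2661,3.4,-6,"(deltaring, rhoCH3) + (deltaring, nuC=O)"
2625,2652,5.5,-27,2deltaring
2600,2633,1.5,-33,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2586,2616,2.4,-30,"(deltaring, deltaCH) + deltaring"
2564,2603,2.8,-39,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2550,2580,3.4,-30,"2(deltaring, deltaCH)"
2536,2547,2.3,-11,"(deltaring, deltaCH) + delta_symCH3"
2505,2506,1.6,-1,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2489,2495,2.7,-6,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2456,2462,1.2,-6,rhoCH3 + delta_asymCH3
2443,2451,2.3,-8,"(deltaring, rhoCH3) + delta_asymCH3"
2414,2432,2.2,-18,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2396,2418,1.6,-22,rhoCH3 + delta_symCH3
2378,2381,2.1,-3,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2371,2370,4.1,1,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2330,2333,4.1,-3,"2(deltaring, deltaCH)"
2318,2323,2.9,-5,"2(deltaring, deltaCH); (deltaring, deltaCH) + (deltaring, deltaCH)"
2292,2298,1.3,-6,"deltaring (breath) + (deltaring, deltaCH)"
2275,2282,2.1,-7,"deltaring + (deltaring, deltaCH)"
2270,2275,2.1,-5,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2250,2255,2.2,-5,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2223,2217,1.8,6,"2(deltaring, deltaCH)"
2203,2204,2.8,-1,"deltaring + (deltaring, deltaCH)"
2188,2176,2.3,12,"deltaring + (deltaring, deltaCH)"
2172,2163,1.8,9,"deltaring + (deltaring, nuC=O)"
2143,2140,3.1,3,"(deltaring, rhoCH3) + (deltaring, deltaCH)"
2111,2123,1.6,-12,"(deltaring, rhoCH3) + (deltaring, deltaCH)"
2114,2110,1.2,4,"(deltaring, rhoCH3) + (deltaring, deltaCH)"
2098,2089,2.3,9,"(deltaring, rhoCH3) + (deltaring, deltaCH)"
2093,2080,1.5,13,2rhoCH3
2074,2057,1.9,17,"deltaring + (deltaring, deltaCH)"
2058,2052,1.6,6,"deltaring + (deltaring, nuC=O)"
2029,2030,1.4,-1,"(deltaring, rhoCH3) + (deltaring, deltaCH)"
2008,2009;1997,4.6;9.0,-1;11,"deltaring + (deltaring, deltaCH); 2gammaCH"
1981,1977,12.0,4,gammaCH + gammaCH
1954,1959,3.5,-5,2gammaCH
1946,1943,2.2,3,"deltaring + (deltaring, deltaCH)"
1903,1913;1905,5.0;6.8,-10;-2,gammaCH + gammaCH
1877,1892;1884,6.5;9.1,-15;-7,gammaCH + gammaCH
1840,1860,1.9,-20,"deltaring + (deltaring, deltaCH)"
1825,1824,5.6,1,2gammaCH
1810,1817;1807,7.8;9.0,-7;3,"gammaCH + gammaCH; deltaring + (deltaring, deltaCH)"
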