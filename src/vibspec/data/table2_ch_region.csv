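exp_positions,exp_intensity,calc_positions,calc_intensity,difference,fundamental,assignment
,,3376,11.0,,0,"2(deltaring, nuC=O)"
3310,40.7,3360,35.1,-50,0,"(deltaring, nuC=O) + (deltaring, nuC=O); 2(deltaring, nuC=O)"
3272,30.4,3331,10.2,-59,0,"(deltaring, nuC=O) + (deltaring, nuC=O)"
3234,11.9,3285,3.5,-51,0,"2(deltaring, nuC=O)"
3183,16.7,3183,8.8,0,0,"(deltaring, deltaCH) + (deltaring, deltaCH)"
3173,19.8,3167,22.9,6,0,"2(deltaring, deltaCH)"
3152,19.9,3141,15.9,11,0,"deltaCH + (deltaring, nuC=O)"
3126,27.7,3127,14.3,-1,0,"deltaCH + (deltaring, nuC=O)"
3095,54.1,3105,12.9,-10,0,"deltaCH + (deltaring, deltaCH)"
3075;3070,88.0;100.0,3063,100.0,12;7,0,"nuCH; delta_symCH3 + (deltaring, nuC=O)"
3046;3038,64.1;65.6,3037,60.2,9;1,1,nuCH
3017;3009,43.5;45.8,3003,21.6,14;6,1,nuCH
2979,50.6,2984,49.1,-5,1,nu_asCH3
2958,64.5,2942,51.6,16,1,nu_asCH3
2920,79.5,2934,54.9,-14,1,nu_sCH3
2892,21.9,2897,8.7,-5,0,"deltaring + (deltaring, deltaCH)"
2878,20.2,2886,7.9,-8,0,"(deltaring, deltaCH) + (deltaring, deltaCH)"
2860,16.1,2861,10.9,-1,0,2delta_asymCH3
2842,21.8,2832,12.4,10,0,2delta_asymCH3
2813,9.3,2817,6.7,-4,0,delta_symCH3 + delta_asymCH3
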