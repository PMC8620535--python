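exp_positions,calc_positions,calc_intensity,difference,assignment
3998,3994,1.6,4,"(deltaring, rhoCH3) + nu_asCH3"
3970,3981,1.5,-11,deltaring + nuCH
3951,3956,1.5,-5,rhoCH3 + nu_sCH3
3940,3933,0.9,7,"(deltaring, rhoCH3) + nu_sCH3"
3868,3854,1.6,14,"(deltaring, rhoCH3) + nuCH"
3859,3834,2.5,25,"(deltaring, rhoCH3) + nuCH"
3802;3788,3781,0.6,21;7,deltaring + nuCH
3748,3755,0.9,-7,deltaring + nuCH
3718,3721,1.2,-3,deltaring + nuCH
3687,3694,0.8,-7,deltaring + nuCH
3663,3655,0.2,8,deltaring + nu_asCH3
3627,3635,0.2,-8,deltaring + nu_asCH3
3610,3620,0.4,-10,"(gammaring, rhoCH3) + nu_asCH3"
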