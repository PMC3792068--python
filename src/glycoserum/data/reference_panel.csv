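code,hex,hexnac,fuc,neuac,theoretical_mz,label
5200,5,2,0,0,1362.481049,1362
3400,3,4,0,0,1444.534147,1444
6200,6,2,0,0,1524.533873,1524
5300,5,3,0,0,1565.560422,1565
3410,3,4,1,0,1590.592056,1590
4400,4,4,0,0,1606.586971,1606
3500,3,5,0,0,1647.61352,1647
7200,7,2,0,0,1686.586697,1686
5310,5,3,1,0,1711.618331,1711
4410,4,4,1,0,1752.64488,1752
5400,5,4,0,0,1768.639795,1768
3510,3,5,1,0,1793.671429,1793
8200,8,2,0,0,1848.639521,1848
5301,5,3,0,1,1870.671489,1870
4401,4,4,0,1,1911.698038,1911
5410,5,4,1,0,1914.697704,1914
9200,9,2,0,0,2010.692345,2010
5311,5,3,1,1,2016.729398,2016
4411,4,4,1,1,2057.755947,2057
5401,5,4,0,1,2073.750862,2073
6410,6,4,1,0,2076.750528,2076
6311,6,3,1,1,2178.782222,2178
4402,4,4,0,2,2216.809105,2216
5411,5,4,1,1,2219.808771,2219
6401,6,4,0,1,2235.803686,2235
6510,6,5,1,0,2279.829901,2279
4412,4,4,1,2,2362.867014,2362
5402,5,4,0,2,2378.861929,2378
6411,6,4,1,1,2381.861595,2381
7401,7,4,0,1,2397.85651,2397
5511,5,5,1,1,2422.888144,2422
6501,6,5,0,1,2438.883059,2438
6312,6,3,1,2,2483.893289,2483
5412,5,4,1,2,2524.919838,2524
6402,6,4,0,2,2540.914753,2540
7411,7,4,1,1,2543.914419,2543
6511,6,5,1,1,2584.940968,2584
7610,7,6,1,0,2644.962098,2644
6412,6,4,1,2,2686.972662,2686
7402,7,4,0,2,2702.967577,2702
6502,6,5,0,2,2743.994126,2743
7601,7,6,0,1,2804.015256,2804
7412,7,4,1,2,2849.025486,2849
6512,6,5,1,2,2890.052035,2890
7611,7,6,1,1,2950.073165,2950
6503,6,5,0,3,3049.105193,3049
7512,7,5,1,2,3052.104859,3052
7602,7,6,0,2,3109.126323,3109
6513,6,5,1,3,3195.163102,3195
7612,7,6,1,2,3255.184232,3255
6523,6,5,2,3,3341.221011,3341
7603,7,6,0,3,3414.23739,3414
7613,7,6,1,3,3560.295299,3560
7623,7,6,2,3,3706.353208,3706
7604,7,6,0,4,3719.348457,3719
7614,7,6,1,4,3865.406366,3865
8604,8,6,0,4,3881.401281,3881
7624,7,6,2,4,4011.464275,4011
8614,8,6,1,4,4027.45919,4027
9604,9,6,0,4,4043.454105,4043
7634,7,6,3,4,4157.522184,4157
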