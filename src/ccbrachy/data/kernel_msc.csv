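# generation,msc
cos_hi,cos_lo,C,c,F,f,rms
1,0.958333333,0.0137178127,0.0558911963,-0.00525699285,0.127593892,0.01656
0.958333333,0.916666667,0.0126674229,0.0558911963,-0.00527541672,0.127593892,0.01726
0.916666667,0.875,0.0118193674,0.0558911963,-0.00527690187,0.127593892,0.01887
0.875,0.833333333,0.0111185752,0.0558911963,-0.00534779958,0.127593892,0.02149
0.833333333,0.791666667,0.0105344045,0.0558911963,-0.00546533238,0.127593892,0.02279
0.791666667,0.75,0.0100488155,0.0558911963,-0.005596816,0.127593892,0.02565
0.75,0.708333333,0.00939638048,0.0558911963,-0.00535894121,0.127593892,0.0198
0.708333333,0.666666667,0.00898219063,0.0558911963,-0.00528901705,0.127593892,0.02535
0.666666667,0.625,0.00859884292,0.0558911963,-0.00533034778,0.127593892,0.02649
0.625,0.583333333,0.00816398356,0.0558911963,-0.00516733154,0.127593892,0.01978
0.583333333,0.541666667,0.00785680975,0.0558911963,-0.00518550369,0.127593892,0.02697
0.541666667,0.5,0.00757374336,0.0558911963,-0.00517297926,0.127593892,0.02659
0.5,0.458333333,0.00731416162,0.0558911963,-0.00509946649,0.127593892,0.02746
0.458333333,0.416666667,0.0069803068,0.0558911963,-0.00491526768,0.127593892,0.02497
0.416666667,0.375,0.00679148943,0.0558911963,-0.0049048865,0.127593892,0.02935
0.375,0.333333333,0.00657827239,0.0558911963,-0.0048515243,0.127593892,0.02991
0.333333333,0.291666667,0.00640861149,0.0558911963,-0.00478887806,0.127593892,0.03195
0.291666667,0.25,0.00620365586,0.0558911963,-0.00467863946,0.127593892,0.03146
0.25,0.208333333,0.00607829028,0.0558911963,-0.00467344696,0.127593892,0.03188
0.208333333,0.166666667,0.00588531792,0.0558911963,-0.00453985917,0.127593892,0.03031
0.166666667,0.125,0.00579306738,0.0558911963,-0.00452798016,0.127593892,0.03274
0.125,0.0833333333,0.00562400493,0.0558911963,-0.0044162357,0.127593892,0.03198
0.0833333333,0.0416666667,0.00550066674,0.0558911963,-0.00434553888,0.127593892,0.03096
0.0416666667,0,0.00543248394,0.0558911963,-0.00432479575,0.127593892,0.03293
0,-0.0416666667,0.00528941092,0.0558911963,-0.00420829355,0.127593892,0.03253
-0.0416666667,-0.0833333333,0.00516624003,0.0558911963,-0.00410745542,0.127593892,0.03225
-0.0833333333,-0.125,0.00511397434,0.0558911963,-0.0040934273,0.127593892,0.03217
-0.125,-0.166666667,0.00499836397,0.0558911963,-0.00399488739,0.127593892,0.03158
-0.166666667,-0.208333333,0.00490403867,0.0558911963,-0.00391916855,0.127593892,0.03278
-0.208333333,-0.25,0.00483376134,0.0558911963,-0.00384487727,0.127593892,0.03423
-0.25,-0.291666667,0.00476012429,0.0558911963,-0.00379037818,0.127593892,0.03485
-0.291666667,-0.333333333,0.00468453345,0.0558911963,-0.00371484729,0.127593892,0.03485
-0.333333333,-0.375,0.00460046473,0.0558911963,-0.0036327543,0.127593892,0.03563
-0.375,-0.416666667,0.00455451622,0.0558911963,-0.00360735961,0.127593892,0.03586
-0.416666667,-0.458333333,0.00447716274,0.0558911963,-0.00353077188,0.127593892,0.0338
-0.458333333,-0.5,0.00444001744,0.0558911963,-0.00347970668,0.127593892,0.03841
-0.5,-0.541666667,0.0043766898,0.0558911963,-0.0034129518,0.127593892,0.03709
-0.541666667,-0.583333333,0.00431771295,0.0558911963,-0.00335521898,0.127593892,0.04015
-0.583333333,-0.625,0.00426073189,0.0558911963,-0.00328207318,0.127593892,0.04116
-0.625,-0.666666667,0.0042289154,0.0558911963,-0.00323490878,0.127593892,0.04154
-0.666666667,-0.708333333,0.00416620624,0.0558911963,-0.00317067054,0.127593892,0.03877
-0.708333333,-0.75,0.00415510247,0.0558911963,-0.00316446874,0.127593892,0.04348
-0.75,-0.791666667,0.00412511201,0.0558911963,-0.00314001833,0.127593892,0.04461
-0.791666667,-0.833333333,0.00409216719,0.0558911963,-0.00310539509,0.127593892,0.04214
-0.833333333,-0.875,0.0040628313,0.0558911963,-0.00307589689,0.127593892,0.04096
-0.875,-0.916666667,0.0040382945,0.0558911963,-0.00306980831,0.127593892,0.03677
-0.916666667,-0.958333333,0.00402462328,0.0558911963,-0.00303463651,0.127593892,0.0414
-0.958333333,-1,0.00401269923,0.0558911963,-0.00302009982,0.127593892,0.04383
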