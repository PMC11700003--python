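# generation,1sc
cos_hi,cos_lo,C,c,F,f,rms
1,0.958333333,0.0109698108,0.104157642,0,0.145585208,0.02595
0.958333333,0.916666667,0.00884900319,0.104157642,0.000790395644,0.145585208,0.02688
0.916666667,0.875,0.00734270292,0.104157642,0.00108900026,0.145585208,0.02998
0.875,0.833333333,0.00597199578,0.104157642,0.00137479725,0.145585208,0.02716
0.833333333,0.791666667,0.00487304105,0.104157642,0.00161517746,0.145585208,0.03363
0.791666667,0.75,0.00411247456,0.104157642,0.00167689637,0.145585208,0.03979
0.75,0.708333333,0.00373009175,0.104157642,0.00126821906,0.145585208,0.03466
0.708333333,0.666666667,0.00286498706,0.104157642,0.00174905879,0.145585208,0.03485
0.666666667,0.625,0.00259101804,0.104157642,0.00149568219,0.145585208,0.04334
0.625,0.583333333,0.00211222924,0.104157642,0.00159420537,0.145585208,0.0378
0.583333333,0.541666667,0.00181790886,0.104157642,0.00150258458,0.145585208,0.03518
0.541666667,0.5,0.00146623205,0.104157642,0.00156432425,0.145585208,0.03926
0.5,0.458333333,0.00131853645,0.104157642,0.00144509451,0.145585208,0.04206
0.458333333,0.416666667,0.00126427014,0.104157642,0.00122973173,0.145585208,0.04465
0.416666667,0.375,0.00103449103,0.104157642,0.00127728484,0.145585208,0.04571
0.375,0.333333333,0.000856446902,0.104157642,0.00129621,0.145585208,0.04232
0.333333333,0.291666667,0.000766071357,0.104157642,0.00124979316,0.145585208,0.04395
0.291666667,0.25,0.000707227141,0.104157642,0.00116398826,0.145585208,0.05212
0.25,0.208333333,0.000616958635,0.104157642,0.0011185762,0.145585208,0.05042
0.208333333,0.166666667,0.000497548137,0.104157642,0.00116762759,0.145585208,0.05178
0.166666667,0.125,0.000482922614,0.104157642,0.00107692417,0.145585208,0.04338
0.125,0.0833333333,0.000463797624,0.104157642,0.000991274441,0.145585208,0.04921
0.0833333333,0.0416666667,0.000352276649,0.104157642,0.00103405401,0.145585208,0.05796
0.0416666667,0,0.000308567918,0.104157642,0.00104741731,0.145585208,0.04906
0,-0.0416666667,0.000306322787,0.104157642,0.000973969811,0.145585208,0.05468
-0.0416666667,-0.0833333333,0.000309876878,0.104157642,0.000903373274,0.145585208,0.05504
-0.0833333333,-0.125,0.000192598489,0.104157642,0.00101610928,0.145585208,0.05306
-0.125,-0.166666667,0.000202473858,0.104157642,0.000947773823,0.145585208,0.04614
-0.166666667,-0.208333333,0.00016357717,0.104157642,0.000974311959,0.145585208,0.05104
-0.208333333,-0.25,0.000201367668,0.104157642,0.000891565091,0.145585208,0.05064
-0.25,-0.291666667,0.000141853472,0.104157642,0.00093066762,0.145585208,0.05447
-0.291666667,-0.333333333,0.000153775048,0.104157642,0.000884141377,0.145585208,0.04825
-0.333333333,-0.375,9.65780236e-05,0.104157642,0.000934372296,0.145585208,0.04665
-0.375,-0.416666667,0.000117622116,0.104157642,0.000891013653,0.145585208,0.05394
-0.416666667,-0.458333333,5.7103178e-05,0.104157642,0.000942347241,0.145585208,0.05532
-0.458333333,-0.5,7.4239802e-05,0.104157642,0.000911329107,0.145585208,0.04258
-0.5,-0.541666667,6.94183127e-05,0.104157642,0.000911538933,0.145585208,0.05401
-0.541666667,-0.583333333,2.40794282e-05,0.104157642,0.000938944838,0.145585208,0.04852
-0.583333333,-0.625,2.84565463e-05,0.104157642,0.000925084957,0.145585208,0.05161
-0.625,-0.666666667,3.48051178e-05,0.104157642,0.000910480441,0.145585208,0.05499
-0.666666667,-0.708333333,4.10078333e-05,0.104157642,0.000887504644,0.145585208,0.04762
-0.708333333,-0.75,1.37216768e-05,0.104157642,0.000909573982,0.145585208,0.05504
-0.75,-0.791666667,0,0.104157642,0.000917091739,0.145585208,0.04988
-0.791666667,-0.833333333,0,0.104157642,0.000926593042,0.145585208,0.04965
-0.833333333,-0.875,0,0.104157642,0.000912522541,0.145585208,0.04442
-0.875,-0.916666667,0,0.104157642,0.00090059748,0.145585208,0.05732
-0.916666667,-0.958333333,0,0.104157642,0.000905917417,0.145585208,0.04734
-0.958333333,-1,0,0.104157642,0.000900381706,0.145585208,0.05419
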