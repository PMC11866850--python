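sex,age,rate
men,50,0.0028
men,51,0.0030711099
men,52,0.0033684701
men,53,0.0036946222
men,54,0.0040523539
men,55,0.0044447229
men,56,0.0048750832
men,57,0.005347113
men,58,0.0058648471
men,59,0.0064327108
men,60,0.0070555579
men,61,0.0077387121
men,62,0.0084880128
men,63,0.0093098644
men,64,0.010211292
men,65,0.0112
men,66,0.01228444
men,67,0.01347388
men,68,0.014778489
men,69,0.016209415
men,70,0.017778892
men,71,0.019500333
men,72,0.021388452
men,73,0.023459388
men,74,0.025730843
men,75,0.028222232
men,76,0.030954849
men,77,0.033952051
men,78,0.037239458
men,79,0.040845167
men,80,0.0448
men,81,0.049137759
men,82,0.053895522
men,83,0.059113954
men,84,0.064837662
men,85,0.071115567
men,86,0.07800133
men,87,0.085553808
men,88,0.093837553
men,89,0.10292337
men,90,0.11288893
men,91,0.12381939
men,92,0.1358082
men,93,0.14895783
men,94,0.16338067
men,95,0.1792
men,96,0.19655104
men,97,0.21558209
men,98,0.23645582
men,99,0.25935065
men,100,0.28446227
women,50,0.0018
women,51,0.001974285
women,52,0.0021654451
women,53,0.0023751142
women,54,0.0026050846
women,55,0.0028573219
women,56,0.003133982
women,57,0.0034374298
women,58,0.0037702588
women,59,0.0041353141
women,60,0.0045357158
women,61,0.0049748864
women,62,0.0054565796
women,63,0.0059849129
women,64,0.0065644019
women,65,0.0072
women,66,0.0078971399
women,67,0.0086617803
women,68,0.009500457
women,69,0.010420339
women,70,0.011429288
women,71,0.012535928
women,72,0.013749719
women,73,0.015081035
women,74,0.016541256
women,75,0.018142863
women,76,0.019899545
women,77,0.021826319
women,78,0.023939651
women,79,0.026257608
women,80,0.0288
women,81,0.031588559
women,82,0.034647121
women,83,0.038001828
women,84,0.041681354
women,85,0.04571715
women,86,0.050143712
women,87,0.054998876
women,88,0.060324141
women,89,0.066165025
women,90,0.072571452
women,91,0.079598182
women,92,0.087305274
women,93,0.095758606
women,94,0.10503043
women,95,0.1152
women,96,0.12635424
women,97,0.13858848
women,98,0.15200731
women,99,0.16672542
women,100,0.1828686
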