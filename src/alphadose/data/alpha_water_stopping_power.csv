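# Total stopping power of alpha particles in liquid water.
# Geiger-rule power-law model R(E) = k*E^p calibrated to published CSDA
# ranges of the 211At-chain alphas in water: 48 um at 5.87 MeV, 70 um at 7.45 MeV.
E_MeV,S_MeV_per_um
0.005,4.7555
0.00549836,4.4993
0.00604638,4.2569
0.00664904,4.02756
0.00731175,3.81058
0.00804052,3.60528
0.00884193,3.41105
0.00972322,3.22728
0.0106923,3.05341
0.0117581,2.88891
0.01293,2.73327
0.0142188,2.58602
0.015636,2.4467
0.0171944,2.31488
0.0189082,2.19017
0.0207928,2.07218
0.0228653,1.96054
0.0251443,1.85491
0.0276504,1.75498
0.0304064,1.66043
0.033437,1.57098
0.0367697,1.48634
0.0404346,1.40627
0.0444648,1.3305
0.0488966,1.25882
0.0537702,1.19101
0.0591296,1.12684
0.0650231,1.06613
0.071504,1.00869
0.0786309,0.954352
0.0864682,0.902937
0.0950866,0.854291
0.104564,0.808267
0.114986,0.764722
0.126447,0.723523
0.13905,0.684543
0.152909,0.647664
0.16815,0.612771
0.18491,0.579758
0.20334,0.548524
0.223607,0.518973
0.245894,0.491013
0.270403,0.46456
0.297354,0.439532
0.326992,0.415852
0.359583,0.393449
0.395423,0.372252
0.434836,0.352197
0.478176,0.333222
0.525837,0.31527
0.578247,0.298285
0.635882,0.282215
0.699261,0.267011
0.768958,0.252626
0.845601,0.239016
0.929883,0.226139
1.02257,0.213956
1.12449,0.202429
1.23656,0.191523
1.35981,0.181205
1.49535,0.171443
1.64439,0.162206
1.80829,0.153467
1.98853,0.145199
2.18672,0.137377
2.40468,0.129976
2.64435,0.122973
2.90792,0.116348
3.19776,0.11008
3.51648,0.104149
3.86697,0.0985385
4.2524,0.0932297
4.67624,0.088207
5.14233,0.0834549
5.65487,0.0789588
6.2185,0.0747049
6.83831,0.0706802
7.51989,0.0668724
8.2694,0.0632696
9.09363,0.059861
10,0.056636
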