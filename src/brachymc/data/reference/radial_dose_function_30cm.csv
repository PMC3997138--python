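r_cm,water,cortical_bone,inflated_lung
0.2,0.999,0.978,1.003
0.4,0.997,0.982,1.000
0.6,0.998,0.989,1.000
0.8,1.000,0.995,1.000
1.0,1.000,1.000,1.000
1.2,1.001,1.006,1.001
1.4,1.000,1.006,1.000
1.6,1.003,1.015,1.001
1.8,1.004,1.016,1.002
2.0,1.006,1.018,1.001
2.2,1.001,1.023,1.001
2.4,0.997,1.019,1.000
2.6,1.003,1.022,1.001
2.8,1.004,1.022,1.001
3.0,1.001,1.019,1.000
3.2,0.999,1.017,0.999
3.4,0.997,1.015,0.997
3.6,0.997,1.011,0.997
3.8,0.998,1.004,0.997
4.0,0.996,1.002,0.997
4.2,0.993,1.000,0.996
4.4,0.991,0.995,0.996
4.6,0.988,0.991,0.996
4.8,0.986,0.989,0.994
5.0,0.988,0.983,0.994
5.5,0.979,0.956,0.994
6.0,0.974,0.937,0.993
6.5,0.966,0.914,0.989
7.0,0.955,0.887,0.988
7.5,0.947,0.863,0.984
8.0,0.936,0.830,0.982
8.5,0.923,0.799,0.981
9.0,0.913,0.767,0.974
9.5,0.891,0.736,0.966
10.0,0.872,0.711,0.963
10.5,0.859,0.672,0.959
11.0,0.833,0.636,0.956
11.5,0.820,0.607,0.950
12.0,0.797,0.574,0.947
12.5,0.774,0.536,0.940
13.0,0.746,0.501,0.934
13.5,0.719,0.467,0.926
14.0,0.687,0.421,0.918
14.5,0.651,0.374,0.909
15.0,0.612,0.329,0.900
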