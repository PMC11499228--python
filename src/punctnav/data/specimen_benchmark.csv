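specimen,rms_ct_sli,rms_ct_ct,surface_drift,skeletal_drift
1,0.561,0.872,0.058,0.079
2,0.577,0.391,0.024,0.160
3,0.456,0.283,0.002,0.170
4,0.587,0.385,0.038,0.058
5,0.649,0.514,0.109,0.022
6,0.481,0.714,0.034,0.179
7,0.642,0.182,0.039,0.460
8,0.518,0.163,0.032,0.515
9,0.648,0.157,0.033,0.612
10,0.528,0.287,0.005,0.175
11,0.506,0.295,0.009,0.054
12,0.461,0.220,0.020,0.105
13,0.798,0.783,0.016,0.550
14,0.852,0.501,0.024,0.422
15,0.823,0.671,0.056,0.488
16,0.382,0.192,0.032,0.054
17,0.774,0.762,0.080,0.280
18,0.368,0.191,0.003,0.136
19,0.409,0.329,0.037,0.165
20,0.489,0.247,0.001,0.013
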