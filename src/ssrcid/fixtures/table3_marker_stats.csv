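# Per-locus genetic statistics of the 33 long-core-motif SSR markers scored on
# 66 clonal tea cultivars, transcribed as printed (3-decimal values verbatim,
# including the anomalous TM369 PID 8.58E-07). core=1 flags the six markers
# selected for the fingerprinting panel.
linkage_group,marker,maf,ng,na,ho,pic,pid,core
LG01,TM447,0.470,8,4,0.470,0.510,0.226,0
LG02,TM514,0.796,5,4,0.273,0.286,0.415,0
LG02,TM480,0.660,8,6,0.515,0.481,0.222,0
LG03,TM337,0.409,20,9,0.758,0.722,0.075,0
LG03,TM453,0.553,15,8,0.561,0.562,0.157,0
LG04,TM343,0.697,11,9,0.561,0.475,0.115,0
LG04,TM445,0.432,7,4,0.515,0.554,0.203,0
LG04,TM502,0.508,13,6,0.727,0.655,0.095,0
LG04,TM422,0.220,33,16,0.864,0.864,0.023,0
LG04,TM369,0.424,18,10,0.773,0.706,8.58E-07,0
LG04,TM523,0.811,5,3,0.227,0.297,0.454,0
LG05,TM589,0.477,6,3,0.606,0.550,0.199,0
LG05,TM428,0.386,17,7,0.727,0.720,0.080,0
LG06,TM341,0.356,23,12,0.606,0.765,0.048,0
LG07,TM415,0.288,26,13,0.530,0.801,0.040,0
LG07,TM426,0.280,17,7,0.652,0.761,0.076,0
LG07,TM324,0.402,7,4,0.636,0.577,0.185,1
LG08,TM352,0.674,5,3,0.546,0.431,0.244,0
LG08,TM395,0.660,5,3,0.591,0.432,0.274,0
LG08,TM493,0.576,10,7,0.682,0.585,0.123,0
LG09,TM442,0.523,9,4,0.485,0.560,0.192,1
LG09,TM440,0.432,14,6,0.864,0.683,0.100,0
LG10,TM407,0.667,15,10,0.515,0.527,0.124,0
LG10,TM569,0.386,7,4,0.788,0.594,0.180,1
LG11,TM461,0.296,10,5,0.773,0.685,0.115,1
LG11,TM581,0.538,9,4,0.621,0.580,0.165,1
LG12,TM241,0.417,11,4,0.788,0.650,0.136,0
LG12,TM499,0.758,5,3,0.439,0.338,0.345,0
LG13,TM425,0.932,2,2,0.136,0.119,0.645,0
LG13,TM576,0.833,3,3,0.333,0.245,0.441,0
LG14,TM348,0.379,12,5,0.712,0.660,0.123,0
LG14,TM351,0.568,9,5,0.576,0.549,0.183,1
LG15,TM601,0.773,5,4,0.394,0.337,0.338,0
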