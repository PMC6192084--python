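classifier,row,overall_accuracy,tp_rate,fp_rate,precision,recall
SMO,normal,93.4132,0.975,0.933,0.957,0.975
SMO,serious,,0.067,0.025,0.111,0.067
SMO,overall,,0.934,0.893,0.919,0.934
SMO,overall_norm,,0.521,0.479,0.534,0.521
BayesNet,normal,92.8144,0.962,0.800,0.962,0.962
BayesNet,serious,,0.200,0.038,0.200,0.200
BayesNet,overall,,0.928,0.766,0.928,0.928
BayesNet,overall_norm,,0.581,0.419,0.581,0.581
IBk,normal,94.3114,0.987,1.000,0.955,0.987
IBk,serious,,0.000,0.013,0.000,0.000
IBk,overall,,0.943,0.956,0.912,0.943
IBk,overall_norm,,0.494,0.507,0.478,0.494
Logistic,normal,91.9162,0.947,0.667,0.968,0.947
Logistic,serious,,0.333,0.053,0.227,0.333
Logistic,overall,,0.919,0.639,0.935,0.919
Logistic,overall_norm,,0.640,0.360,0.598,0.640
C4.5,normal,93.1138,0.969,0.867,0.960,0.969
C4.5,serious,,0.133,0.031,0.167,0.133
C4.5,overall,,0.931,0.829,0.924,0.931
C4.5,overall_norm,,0.551,0.449,0.564,0.551
Ripper,normal,93.7126,0.966,0.667,0.969,0.966
Ripper,serious,,0.333,0.034,0.313,0.333
Ripper,overall,,0.937,0.638,0.939,0.937
Ripper,overall_norm,,0.650,0.350,0.641,0.650
NRBNF,normal,94.0120,0.981,0.933,0.957,0.981
NRBNF,serious,,0.067,0.019,0.143,0.067
NRBNF,overall,,0.940,0.892,0.921,0.940
NRBNF,overall_norm,,0.524,0.476,0.550,0.524
Crowd reasoning,normal,94.6108,0.972,0.600,0.972,0.972
Crowd reasoning,serious,,0.400,0.028,0.600,0.400
Crowd reasoning,overall,,0.936,0.564,0.949,0.936
Crowd reasoning,overall_norm,,0.686,0.314,0.786,0.686
Hybrid reasoning,normal,92.5150,0.940,0.400,0.980,0.940
Hybrid reasoning,serious,,0.600,0.060,0.400,0.600
Hybrid reasoning,overall,,0.919,0.378,0.944,0.919
Hybrid reasoning,overall_norm,,0.770,0.230,0.690,0.770
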