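classifier,row,overall_accuracy,tp_rate,fp_rate,precision,recall
SMO,normal,93.4132,0.984,0.773,0.948,0.984
SMO,serious,,0.227,0.016,0.500,0.227
SMO,overall,,0.934,0.723,0.918,0.934
SMO,overall_norm,,0.606,0.395,0.724,0.606
BayesNet,normal,92.8144,0.981,0.818,0.944,0.981
BayesNet,serious,,0.182,0.019,0.400,0.182
BayesNet,overall,,0.928,0.766,0.909,0.928
BayesNet,overall_norm,,0.582,0.419,0.672,0.582
IBk,normal,92.2156,0.981,0.909,0.939,0.981
IBk,serious,,0.091,0.019,0.250,0.091
IBk,overall,,0.922,0.850,0.893,0.922
IBk,overall_norm,,0.536,0.464,0.595,0.536
Logistic,normal,87.4251,0.920,0.773,0.944,0.920
Logistic,serious,,0.227,0.080,0.167,0.227
Logistic,overall,,0.874,0.727,0.893,0.874
Logistic,overall_norm,,0.574,0.427,0.556,0.574
C4.5,normal,88.6228,0.929,0.727,0.948,0.929
C4.5,serious,,0.273,0.071,0.214,0.273
C4.5,overall,,0.886,0.684,0.899,0.886
C4.5,overall_norm,,0.601,0.399,0.581,0.601
Ripper,normal,91.018,0.958,0.773,0.946,0.958
Ripper,serious,,0.227,0.042,0.278,0.227
Ripper,overall,,0.910,0.725,0.902,0.910
Ripper,overall_norm,,0.593,0.408,0.612,0.593
NRBNF,normal,91.6168,0.968,0.818,0.944,0.968
NRBNF,serious,,0.182,0.032,0.286,0.182
NRBNF,overall,,0.916,0.766,0.900,0.916
NRBNF,overall_norm,,0.575,0.425,0.615,0.575
Crowd reasoning,normal,89.8204,0.930,0.545,0.960,0.930
Crowd reasoning,serious,,0.455,0.070,0.545,0.455
Crowd reasoning,overall,,0.900,0.515,0.934,0.900
Crowd reasoning,overall_norm,,0.693,0.308,0.753,0.693
Hybrid reasoning,normal,92.5150,0.926,0.091,0.993,0.926
Hybrid reasoning,serious,,0.909,0.074,0.465,0.909
Hybrid reasoning,overall,,0.924,0.090,0.906,0.924
Hybrid reasoning,overall_norm,,0.918,0.083,0.729,0.918
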