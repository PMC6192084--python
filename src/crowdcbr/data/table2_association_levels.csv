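word,normal,serious,bold
Temperature,0.0005,0.0140,none
Humidity,0.0060,0.0065,none
Noise,0.0003,0.0108,serious
Illumination,0.0034,0.0022,none
Anger,0.0350,0.0006,normal
Stress,0.0277,0.0455,serious
Fatigue,0.0309,0.0329,serious
Fat,0.0064,0.1097,serious
Diabetes,0.0148,0.3164,serious
Heart disease,0.0001,0.0001,none
Hyperlipidemia,0.0014,0.0005,none
Cancer,0.0195,0.0002,none
Smoking,0.0032,0.0169,serious
Drinking,0.0246,0.0641,serious
Indigestion,0.0002,0.0001,none
Insomnia,0.0033,0.0169,serious
Cold,0.0268,0.0002,normal
Allergy,0.0005,0.1639,serious
Neurosis,0.0000,0.0000,none
Blood pressure,0.0006,0.1176,serious
Blood sugar,0.0060,0.0162,none
Wellness,0.0280,0.0329,serious
Age,0.0241,0.0003,normal
Gender,0.0089,0.0070,normal
Weight,0.0324,0.0120,none
Solitude,0.0039,0.0054,none
Hobby,0.0156,0.0001,normal
Yellow dust,0.0006,0.0000,normal
Inconvenience,0.0024,0.0086,none
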