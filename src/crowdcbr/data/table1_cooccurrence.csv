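word,count_alone,normal,serious
Temperature,4870000,876157,3340792
Humidity,1590000,424202,662866
Noise,4120000,842,1892800
Illumination,138000,26554,143341
Anger,1470000,122198,289937
Stress,2450000,3995,7359688
Fatigue,1060000,1817,4209870
Fat,643000,639,6018812
Diabetes,3790000,722403,4987286
Heart disease,920000,209,4101
Hyperlipidemia,28100,34113,29947
Cancer,1500000,1942493,145190
Smoking,202000,555492,1751117
Drinking,328000,796695,4630933
Indigestion,1100000,500,7544
Insomnia,205000,867,896134
Cold,925000,122044,75463
Allergy,2190000,424296,3129584
Neurosis,2400000,67,1901
Blood pressure,6630000,734,2788095
Blood sugar,3700000,792222,880241
Wellness,21600000,71406,5309378
Age,2730000,10044,320237
Gender,248000,736,1599652
Weight,3420000,486809,1465803
Solitude,837000,108093,409730
Hobby,903000,4411,107178
Yellow dust,775000,321,730
Inconvenience,606000,267279,706899
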