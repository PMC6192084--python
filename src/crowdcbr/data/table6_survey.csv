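No,P_GEN,P_AGE,P_AG,P_WEI,P_SOL,P_HOB,P_LOC,C_TEM,C_HUM,C_NOI,C_ACT,C_ILL,C_YD,D_FAT,D_DIA,D_HTD,D_HL,D_CAN,D_SMK,D_ACL,D_INDI,D_DEP,D_INS,D_COLD,D_ALG,D_NEU,D_BP,D_BS,E_ANG,E_STR,E_DEP,E_FTG
1,2,62,6,59,2,2,1,3,3,3,3,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,3,3,3,3
2,2,20,2,50,3,1,1,3,2,4,1,4,4,4,1,1,1,1,1,1,5,2,3,1,1,1,4,1,3,3,5,5
3,1,59,5,62,2,1,1,7,7,7,7,7,7,3,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
4,1,48,4,50,2,3,12,4,4,4,3,4,4,2,2,2,2,2,1,1,5,3,1,1,3,3,1,2,2,4,3,2
5,1,50,5,70,2,1,1,7,6,6,5,6,6,7,6,5,6,7,6,5,6,7,6,6,5,6,6,7,7,6,7,6
6,2,32,3,47,2,1,1,5,5,4,4,4,5,5,1,1,4,1,1,1,5,4,4,3,4,4,4,1,1,2,2,3
7,1,58,5,71,2,3,8,4,4,4,4,4,1,6,3,4,4,1,1,1,5,4,4,5,5,6,6,5,4,5,5,5
8,2,53,5,71,2,3,9,3,3,6,6,6,4,6,5,5,5,2,1,1,6,2,1,1,6,6,6,5,2,2,2,3
9,1,41,4,65,2,1,8,5,5,5,6,5,5,2,2,1,5,1,1,2,3,2,2,2,2,2,4,2,2,2,2,4
10,2,65,6,72,2,1,12,6,6,6,5,6,5,5,5,2,5,1,1,1,3,2,2,2,5,2,6,5,1,1,1,2
11,2,54,5,45,2,1,5,6,5,5,5,5,5,2,5,2,2,2,1,1,2,2,2,2,3,2,2,3,2,2,2,2
12,1,61,6,65,2,3,12,4,4,4,5,4,3,1,1,2,2,1,7,7,5,4,3,3,5,4,4,4,2,3,2,5
13,2,62,6,56,2,4,9,6,6,4,4,6,7,5,1,1,5,1,1,1,1,1,1,1,7,1,5,4,1,1,1,1
14,1,32,3,85,1,2,2,6,6,6,6,6,6,6,1,1,1,1,1,1,3,3,2,1,1,1,7,4,2,4,3,5
15,2,44,4,58,2,2,13,5,4,5,4,4,4,3,1,1,1,1,1,1,1,1,1,4,4,1,1,1,2,3,1,3
16,2,49,4,56,2,3,1,3,3,4,4,4,4,5,1,1,1,1,1,1,3,3,4,4,2,4,4,2,4,4,4,4
17,1,29,2,65,2,1,5,3,3,6,5,5,4,1,1,1,1,1,1,1,3,1,5,1,2,4,1,1,3,4,2,3
18,1,52,5,66,1,2,1,4,4,4,4,4,4,4,3,7,6,1,1,2,2,2,4,2,1,2,5,1,3,3,2,2
19,1,67,6,70,2,3,8,4,4,7,5,4,2,5,1,3,5,1,1,1,3,1,1,1,1,4,7,4,1,3,1,4
20,1,60,6,62,2,1,1,6,6,5,7,6,2,1,6,1,1,1,1,6,1,1,1,5,2,1,1,6,1,3,1,1
21,1,37,3,68,2,2,1,4,4,4,4,5,4,3,3,3,3,4,1,2,3,3,2,3,2,3,4,3,4,4,4,5
22,1,63,6,71,2,3,1,4,5,4,3,5,5,2,2,3,6,2,6,4,6,5,5,3,2,5,4,2,2,5,4,4
23,1,54,5,72,2,2,1,5,5,5,3,6,6,3,6,6,2,1,1,7,1,1,1,1,1,1,6,6,1,1,1,1
24,1,45,4,68,2,1,3,6,6,5,5,5,6,1,1,1,1,1,2,1,1,1,1,1,1,3,1,1,1,1,1,2
25,1,65,6,70,2,2,8,4,4,5,4,4,5,5,2,3,2,1,1,1,3,2,2,2,2,3,3,3,4,4,3,3
26,2,35,3,51,2,3,8,5,4,4,3,4,4,4,4,1,3,1,1,1,3,1,1,1,5,1,1,1,1,4,1,2
27,1,41,4,78,2,1,8,4,4,5,3,5,2,4,2,2,2,2,5,6,2,2,1,3,4,2,3,2,3,5,4,5
28,1,45,4,78,2,1,4,7,7,5,5,6,7,4,4,2,4,2,1,1,1,1,4,2,1,1,6,5,1,1,1,1
29,2,44,4,53,2,2,1,4,4,1,2,5,3,4,1,1,1,1,1,1,4,1,2,1,1,2,1,1,3,3,4,5
30,2,38,3,65,2,2,8,6,6,6,4,6,5,6,1,1,1,1,1,1,1,1,1,1,1,1,4,1,1,1,1,2
31,1,53,5,64,2,2,8,4,4,4,5,4,4,2,1,2,2,1,5,5,1,1,2,1,1,1,2,1,1,1,1,1
32,1,52,5,70,2,1,1,6,6,6,7,7,6,2,4,1,2,1,1,1,1,1,1,1,1,1,4,6,1,1,1,1
33,1,49,4,89,2,2,8,2,2,6,2,6,1,5,1,1,4,1,5,2,1,3,3,1,6,5,7,1,2,5,2,6
34,2,55,5,65,2,2,11,5,5,6,6,6,5,6,4,5,6,1,1,1,1,6,6,1,6,6,6,5,2,3,5,4
35,2,48,4,59,2,2,8,4,4,5,4,5,5,2,1,1,1,1,1,1,1,3,2,4,4,4,1,1,2,2,2,3
36,1,52,5,82,2,2,1,5,5,3,4,5,5,5,2,2,4,2,6,2,4,5,3,3,2,4,7,4,3,3,3,3
37,2,61,6,62,2,2,6,5,6,6,4,6,6,6,1,3,6,1,1,1,2,2,2,4,2,3,7,2,1,2,1,4
38,2,24,2,49,2,1,11,5,5,4,4,5,5,2,1,1,1,1,1,1,4,1,1,1,1,1,4,1,1,2,1,5
39,1,59,5,82,2,3,8,6,5,5,3,5,5,5,5,4,5,2,6,6,1,3,3,3,1,1,5,4,1,2,1,1
40,2,33,3,68,2,2,4,7,7,4,2,5,6,6,1,1,1,1,1,1,1,1,1,1,5,1,1,1,1,1,1,1
41,2,46,4,52,2,3,11,5,5,6,3,5,4,5,1,1,2,1,1,1,3,4,4,4,2,2,2,1,1,6,6,4
42,2,60,6,57,2,2,4,6,6,5,6,6,7,5,2,5,5,2,1,2,5,1,1,2,2,2,6,2,1,1,2,1
43,2,35,3,60,2,1,4,5,5,4,3,6,4,4,4,4,3,2,1,1,4,4,1,5,5,5,4,2,1,2,1,3
44,2,59,5,56,2,2,11,4,4,7,4,7,7,4,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
45,1,47,4,60,2,1,1,4,4,4,4,4,4,1,1,1,1,1,4,6,1,1,1,1,1,1,1,1,1,3,3,5
46,2,43,4,52,2,2,8,6,6,6,5,5,6,2,1,1,1,1,1,1,1,1,1,2,1,1,1,1,1,1,1,1
47,2,32,3,68,2,2,2,7,7,5,4,7,4,7,1,1,5,1,1,1,6,4,4,2,1,1,4,5,1,2,1,2
48,2,50,5,43,2,1,1,6,6,6,4,6,4,1,2,1,5,1,1,1,5,2,2,1,1,5,1,2,1,5,2,2
49,1,60,6,50,2,2,8,4,4,5,3,4,5,1,1,1,1,1,1,1,2,2,2,1,1,1,1,1,2,3,2,3
50,1,29,2,68,2,1,1,5,5,3,3,5,5,1,1,1,1,1,1,1,5,1,1,1,3,5,1,1,2,2,2,2
51,1,67,6,68,2,2,5,5,5,6,3,4,7,3,3,3,4,2,2,5,3,2,6,3,3,3,5,3,1,1,1,1
52,2,27,2,46,2,2,4,6,6,3,4,6,4,2,1,1,1,1,1,1,1,1,1,1,1,2,3,1,1,3,2,2
53,2,53,5,62,2,3,13,6,6,6,5,6,7,3,3,3,3,3,1,1,1,1,1,1,1,1,1,1,1,1,1,1
54,2,41,4,60,2,1,8,5,5,5,3,4,3,4,1,1,1,1,1,1,2,2,3,1,3,2,1,1,2,2,2,3
55,1,33,3,69,2,1,8,6,6,7,2,7,4,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,6,1,5
56,1,43,4,79,2,2,8,6,5,6,3,6,5,5,4,4,4,3,5,5,3,3,4,3,4,4,4,4,4,3,3,4
57,1,51,5,53,2,1,8,3,4,3,3,5,3,1,1,1,1,1,4,3,2,1,1,1,5,5,1,1,4,5,4,4
58,2,29,2,43,1,3,1,4,4,4,2,3,3,1,1,1,1,1,6,2,5,5,4,1,6,3,4,4,1,1,1,5
59,2,32,3,55,2,1,1,4,4,4,4,4,4,1,1,1,1,1,1,4,3,3,1,1,4,4,4,1,1,4,1,4
60,1,35,3,70,2,2,1,5,5,5,4,5,5,2,2,2,2,2,5,3,4,2,2,3,5,5,4,4,3,4,4,3
61,2,40,4,51,2,1,1,5,4,5,5,4,4,1,1,1,1,1,1,1,5,1,1,1,4,1,4,1,3,2,2,2
62,2,45,4,60,2,1,1,6,6,6,6,6,4,2,3,2,5,4,1,4,5,5,5,5,2,5,2,4,1,5,2,2
63,1,26,2,79,2,3,6,3,3,7,3,3,3,1,1,1,1,1,1,1,1,5,6,5,1,4,7,1,5,6,5,7
64,1,62,6,64,2,2,8,4,5,3,2,6,6,1,4,2,3,2,1,1,3,2,4,3,2,2,5,5,2,3,2,4
65,2,32,3,49,2,3,6,4,2,2,2,4,3,1,1,1,1,1,1,1,1,5,1,1,1,4,4,1,1,4,2,5
66,2,58,5,50,2,2,14,5,5,6,4,4,5,1,1,5,1,1,1,1,4,1,1,1,1,1,1,1,2,2,2,2
67,2,61,6,72,2,1,15,6,6,5,6,5,6,3,3,3,3,1,1,1,4,6,1,6,6,7,6,4,5,5,6,6
68,2,23,2,80,2,1,4,6,3,5,1,4,3,6,1,3,1,1,1,3,6,6,6,5,7,6,1,5,1,5,5,5
69,2,60,6,52,2,1,2,7,7,7,2,7,7,1,1,7,7,1,1,1,4,1,6,1,1,1,1,7,1,1,1,1
70,2,45,4,54,2,2,6,6,6,7,5,6,6,5,5,2,5,1,1,1,1,1,1,1,1,4,5,5,2,6,5,5
71,2,24,2,53,1,2,6,4,4,4,3,4,5,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
72,1,53,5,69,2,2,4,5,5,5,5,5,5,2,2,1,2,1,4,2,1,1,1,1,1,3,2,2,2,2,1,4
73,2,35,3,60,2,3,14,4,3,3,4,4,3,5,1,1,1,1,1,1,1,1,1,1,1,1,1,1,3,5,4,5
74,2,59,5,57,2,2,1,6,6,4,5,6,6,3,1,1,3,1,1,1,3,1,1,2,1,2,5,1,1,1,1,3
75,2,22,2,53,2,2,8,7,7,7,1,7,7,1,2,1,1,1,1,1,1,1,2,1,1,1,1,1,1,1,1,1
76,2,29,2,70,2,2,12,4,3,2,3,4,2,5,1,1,1,1,1,1,2,2,2,1,3,2,4,3,1,3,2,3
77,1,65,6,60,2,2,1,1,1,7,7,7,1,1,1,1,1,1,5,1,1,1,1,1,1,1,6,1,1,1,1,1
78,1,66,6,68,2,1,15,7,4,6,7,5,7,1,1,1,1,1,1,1,2,4,2,4,5,3,5,1,1,1,1,1
79,1,42,4,54,2,3,8,4,4,4,4,4,4,2,2,2,2,1,1,1,5,4,6,5,3,3,3,2,3,3,3,4
80,1,62,6,62,2,2,7,5,5,5,3,5,5,2,6,2,2,2,2,2,2,2,2,2,2,2,2,6,2,2,2,2
81,2,20,2,60,2,2,4,6,5,4,5,5,2,6,1,1,1,1,1,1,4,5,4,6,6,6,4,4,5,2,2,2
82,1,35,3,75,2,2,8,6,4,5,6,5,4,5,1,1,1,1,7,6,2,1,3,4,1,5,5,1,1,2,1,5
83,2,30,3,61,2,3,11,5,5,5,5,6,5,2,1,1,1,1,1,1,1,2,1,1,1,1,1,1,2,5,5,5
84,1,42,4,57,2,1,1,4,4,4,4,4,5,1,2,4,6,1,1,2,3,5,5,1,2,3,3,3,5,5,5,5
85,2,31,3,75,2,1,1,7,7,1,4,7,7,7,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
86,2,19,2,46,2,3,15,3,4,3,2,2,2,1,1,1,1,1,1,1,1,3,3,1,4,1,1,1,2,3,5,5
87,2,25,2,70,2,1,8,7,7,2,2,5,2,7,6,1,6,5,7,7,7,3,3,7,1,7,7,6,1,6,4,7
88,1,38,3,87,2,2,12,5,5,6,4,5,5,5,4,1,2,1,6,2,1,1,1,2,1,1,2,1,1,2,1,1
89,1,51,5,80,2,2,11,3,3,4,4,4,4,6,4,4,4,4,4,4,5,4,4,4,4,4,6,4,3,4,4,4
90,1,64,6,74,2,2,8,4,4,5,5,5,4,6,6,5,5,4,1,3,3,5,5,5,3,4,4,3,5,5,5,5
91,2,34,3,55,2,2,1,5,5,5,3,5,5,1,1,1,1,1,1,1,1,1,1,1,2,1,4,1,1,4,2,2
92,1,59,5,62,2,2,1,5,5,4,3,5,3,1,2,3,3,2,5,3,2,1,2,3,2,1,3,3,1,2,2,2
93,1,37,3,78,1,1,1,5,5,5,5,6,5,5,1,1,1,1,4,1,4,1,4,1,1,1,5,1,5,5,4,5
94,2,51,5,58,2,3,5,3,3,5,6,5,5,4,1,1,1,1,1,1,3,3,6,2,1,2,1,1,1,2,2,3
95,1,35,3,72,2,2,8,5,5,5,6,5,5,2,1,1,1,1,1,1,1,1,1,1,1,1,1,1,2,2,1,3
96,1,38,3,74,1,3,1,4,4,5,4,4,4,4,3,4,3,3,2,5,4,5,3,3,3,5,4,4,4,5,5,4
97,2,60,6,58,2,2,1,4,5,5,5,6,6,3,1,1,2,1,1,1,1,1,1,1,3,2,1,1,3,3,3,3
98,2,51,5,57,2,2,8,5,5,5,6,5,4,5,1,1,5,1,1,1,5,4,1,1,5,1,5,3,2,2,2,3
99,2,60,6,54,2,1,8,4,4,5,3,4,4,4,2,4,5,3,2,2,2,2,2,4,2,2,4,2,2,4,2,3
100,2,65,6,55,2,2,3,5,4,6,6,5,3,2,2,1,5,1,1,4,2,4,6,4,4,4,4,4,3,6,6,5
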