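id,substituents,inhibition_pct,ic50_uM,role
1,3-acetyl;6-bromo,28.5,,modeling
2,3-acetyl;6-hydroxy,12.8,,excluded_outlier
3,3-acetyl;7-diethylamino,,,excluded_inactive
4,3-acetyl;7-hydroxy,16.2,,modeling
5,3-acetyl;8-ethoxy,,,modeling
6,3-acetyl;8-hydroxy,,,excluded_inactive
7,3-acetyl,7.8,,modeling
8,3-benzoyl;6-chloro,4.4,,modeling
9,3-benzoyl;6-bromo;8-bromo,,,excluded_inactive
10,3-benzoyl;6-hydroxy,67.5,,modeling
11,3-benzoyl;7-benzoyl,22.8,,modeling
12,3-benzoyl;7-hydroxy,100.0,1.10,modeling
13,3-benzoyl;7-methoxy,16.5,,modeling
14,3-benzoyl;8-ethoxy,,,excluded_inactive
15,3-benzoyl,9.6,,modeling
16,3-cyano;6-bromo,7.9,,modeling
17,3-cyano;6-methoxy,19.8,,modeling
18,3-cyano;6-hydroxy,44.6,,modeling
19,3-cyano;7-benzoyl,7.1,,modeling
20,3-cyano;7-methoxy,,,excluded_inactive
21,3-cyano;8-hydroxy,62.6,,modeling
22,3-cyano;8-ethoxy,,,modeling
23,3-cyano,,,excluded_inactive
24,3-ethoxycarbonyl;6-bromo,,,excluded_inactive
25,3-ethoxycarbonyl;6-chloro,20.1,,modeling
26,3-ethoxycarbonyl;6-dihydroxyamino,59.7,,modeling
27,3-ethoxycarbonyl;6-hydroxy,66.0,,modeling
28,3-ethoxycarbonyl;6-bromo;8-bromo,29.4,,modeling
29,3-ethoxycarbonyl;7-methoxy,,,modeling
30,3-ethoxycarbonyl;8-ethoxy,,,modeling
31,3-ethoxycarbonyl,,,excluded_inactive
32,3-methoxycarbonyl;6-bromo,6.5,,modeling
33,3-methoxycarbonyl;6-dihydroxyamino,21.2,,modeling
34,3-methoxycarbonyl;6-hydroxy,23.5,,modeling
35,3-methoxycarbonyl;6-methoxy,9.9,,modeling
36,3-methoxycarbonyl;7-hydroxy,100.0,2.14,modeling
37,3-methoxycarbonyl;7-methoxy,,,modeling
38,3-methoxycarbonyl,2.3,,modeling
39,,,,modeling
40,7-hydroxy,2.1,,modeling
41,3-benzoyl;5-hydroxy;7-hydroxy,,,proposed
42,3-benzoyl;6-hydroxy;8-hydroxy,,,proposed
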