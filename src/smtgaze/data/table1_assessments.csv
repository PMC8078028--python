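subject,age,gender,glasses,moca,tmt_a,tmt_b,snmt,iadl
1,73,m,yes,26,23.85,173.00,25.53,8
2,72,m,no,27,22.06,108.00,25.86,8
3,66,m,yes,27,18.18,54.07,,6
4,80,m,no,26,21.92,85.45,36.12,8
5,71,m,yes,27,21.80,84.50,52.26,8
6,65,m,yes,30,17.26,51.15,34.10,8
7,70,f,yes,29,19.38,118.89,27.48,8
8,68,f,no,27,20.05,85.00,30.95,7
9,76,m,yes,29,18.51,89.49,17.83,8
10,73,m,yes,27,21.60,128.74,28.46,7
11,71,f,no,28,25.80,80.00,49.00,8
12,63,f,no,30,12.10,47.05,15.43,7
13,73,f,no,27,28.20,63.00,27.00,8
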