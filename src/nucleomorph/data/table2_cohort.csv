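case_id,specimen,group,timepoint,ki67_pct,p53_pct,nacv,tmb
1,P,non_recurrent,0,4.18,2.51,31.83,0.41
2,P,non_recurrent,0,10.68,10.01,35.47,0.68
3,P,non_recurrent,0,7.53,7.43,30.32,0.09
4,P,non_recurrent,0,0.44,2.57,24.51,0.38
5,P,non_recurrent,0,2.82,24.13,24.71,0.18
6,P,non_recurrent,0,2.09,0.00,35.10,0.21
7,P,non_recurrent,0,1.67,0.17,53.43,0.12
12,P,non_recurrent,0,7.12,0.00,37.09,10.35
8,P,recurrent_case,0,1.68,0.00,30.79,0.76
8,R1,recurrent_case,1,2.78,14.14,26.11,0.18
8,R2,recurrent_case,2,6.38,11.21,23.33,1.71
8,R3,recurrent_case,3,7.28,11.32,22.59,2.91
8,R4,recurrent_case,4,8.98,24.98,41.54,3.44
9,P,recurrent_case,0,7.62,0.00,31.05,1.88
9,R1,recurrent_case,1,3.26,0.31,33.97,8.44
9,R2,recurrent_case,2,9.01,0.00,40.67,NS
9,R3,recurrent_case,3,8.85,0.00,27.74,12.62
9,R4,recurrent_case,4,7.05,0.00,49.89,0.97
10,P,recurrent_case,0,9.96,7.10,25.99,0.06
10,R1,recurrent_case,1,0.08,0.01,25.78,NS
10,R2,recurrent_case,2,14.69,3.45,31.44,13.88
11,P,recurrent_case,0,0.18,0.00,17.90,NS
11,R1,recurrent_case,1,4.88,0.00,26.59,7.53
11,R2,recurrent_case,2,9.25,0.00,27.46,8.56
11,R3,recurrent_case,3,9.30,0.00,32.10,3.65
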