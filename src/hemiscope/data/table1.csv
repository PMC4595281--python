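patient,age,tps_months,gender,hand,hemisphere,location,fm,arat,nhpt_pct
1,42,26,F,L,L,SC,66,57,86
2,52,24,M,R,R,P,61,57,80
3,53,46,F,R,L,C,61,57,76
4,47,45,M,R,R,SC,56,52,72
5,67,31,M,R,L,SC,63,57,62
6,67,33,M,R,R,SC,53,56,65
7,73,22,M,R,R,P,66,57,125
8,57,36,M,R,L,C,58,57,65
9,57,41,M,A,R,SC,65,57,84
10,60,14,M,,R,SC,66,57,67
11,50,5,M,R,R,SC,59,57,69
12,73,22,M,R,L,C,44,50,57
13,48,39,M,R,L,SC,57,53,18
14,73,113,M,R+,R,SC,66,57,100
15,49,26,M,R,L,SC,55,57,58
16,40,128,F,L,R,SC,64,57,46
17,64,20,M,R+,L,SC,61,57,82
18,59,21,F,R,L,SC,61,53,34
19,45,11,M,R,L,P,61,57,70
20,53,14,F,R,R,SC,66,57,65
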