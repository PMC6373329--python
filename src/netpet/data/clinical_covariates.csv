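patient,sex,age_y,dd_y,hy,updrs3_off,updrs3_on,ledd_mg
1,M,59,16,2,30,13,405
2,M,59,3,1,14,3,408
3,M,73,2,3,28,10,450
4,M,65,6,3,36,19,720
5,F,54,2,1,11,6,260
6,M,53,4,1,22,15,557
7,F,61,3,1,25,18,450
8,M,53,3,2,20,16,720
9,M,64,2,1,11,8,780
10,M,64,3,1,15,9,310
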