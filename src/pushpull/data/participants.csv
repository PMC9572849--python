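participant_id,age,weight,height,dass_stress_total,dass_anxiety_total,dass_depression_total,apathy_total,straight_leg_raise_positive,reduced_rom,trigger_point_count
1,28,110,185,10,0,0,4,0,0,0
2,40,100,202,12,6,1,16,0,1,0
3,41,102,188,13,4,4,15,0,1,0
4,36,92,190,5,1,0,15,0,1,5
5,26,65,163,5,5,8,17,0,0,0
6,30,100,194,12,8,11,11,0,1,4
7,35,92,178,15,1,2,15,0,1,6
8,37,115,188,13,6,3,16,0,0,0
9,52,94,184,8,6,0,10,0,0,0
10,38,90,190,15,6,5,14,0,0,0
11,35,99,186,11,9,4,16,0,1,5
12,34,80,175,10,1,1,10,0,0,2
13,33,92,186,16,7,4,16,0,1,2
14,38,100,190,6,4,2,13,0,1,2
15,33,105,190,9,1,0,13,0,1,0
16,30,97,193,14,8,3,16,0,0,0
17,29,94,192,8,4,5,14,0,1,1
18,30,101,198,10,7,8,17,0,0,0
19,34,85,174,16,6,4,21,0,1,0
20,35,85,187,9,2,1,12,0,0,2
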