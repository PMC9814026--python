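group,time,status,age,female,GN,AN,PKD
1,8,1,28,0,0,0,0
1,16,1,28,0,0,0,0
2,23,1,48,1,1,0,0
2,13,0,48,1,1,0,0
3,22,1,32,0,0,0,0
3,28,1,32,0,0,0,0
4,447,1,31,1,0,0,0
4,318,1,32,1,0,0,0
5,30,1,10,0,0,0,0
5,12,1,10,0,0,0,0
6,24,1,16,1,0,0,0
6,245,1,17,1,0,0,0
7,7,1,51,0,1,0,0
7,9,1,51,0,1,0,0
8,511,1,55,1,1,0,0
8,30,1,56,1,1,0,0
9,53,1,69,1,0,1,0
9,196,1,69,1,0,1,0
10,15,1,51,0,1,0,0
10,154,1,52,0,1,0,0
11,7,1,44,1,0,1,0
11,333,1,44,1,0,1,0
12,141,1,34,1,0,0,0
12,8,0,34,1,0,0,0
13,96,1,35,1,0,1,0
13,38,1,35,1,0,1,0
14,149,0,42,1,0,1,0
14,70,0,42,1,0,1,0
15,536,1,17,1,0,0,0
15,25,0,17,1,0,0,0
16,17,1,60,0,0,1,0
16,4,0,60,0,0,1,0
17,185,1,60,1,0,0,0
17,177,1,60,1,0,0,0
18,292,1,43,1,0,0,0
18,114,1,44,1,0,0,0
19,22,0,53,1,1,0,0
19,159,0,53,1,1,0,0
20,15,1,44,1,0,0,0
20,108,0,44,1,0,0,0
21,152,1,46,0,0,0,1
21,562,1,47,0,0,0,1
22,402,1,30,1,0,0,0
22,24,0,30,1,0,0,0
23,13,1,62,1,0,1,0
23,66,1,63,1,0,1,0
24,39,1,42,1,0,1,0
24,46,0,43,1,0,1,0
25,12,1,43,0,0,1,0
25,40,1,43,0,0,1,0
26,113,0,57,1,0,1,0
26,201,1,58,1,0,1,0
27,132,1,10,1,1,0,0
27,156,1,10,1,1,0,0
28,34,1,52,1,0,1,0
28,30,1,52,1,0,1,0
29,2,1,53,0,1,0,0
29,25,1,53,0,1,0,0
30,130,1,54,1,1,0,0
30,26,1,54,1,1,0,0
31,27,1,56,1,0,1,0
31,58,1,56,1,0,1,0
32,5,0,50,1,0,1,0
32,43,1,51,1,0,1,0
33,152,1,57,1,0,0,1
33,30,1,57,1,0,0,1
34,190,1,44,1,1,0,0
34,5,0,45,1,1,0,0
35,119,1,22,1,0,0,0
35,8,1,22,1,0,0,0
36,54,0,42,1,0,0,0
36,16,0,42,1,0,0,0
37,6,0,52,1,0,0,1
37,78,1,52,1,0,0,1
38,63,1,60,0,0,0,1
38,8,0,60,0,0,0,1
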