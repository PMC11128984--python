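percent,date,count
0,2023-07-22,2215
0,2023-07-23,2451
0,2023-07-24,2360
0,2023-07-25,2290
0,2023-07-26,2443
0,2023-07-27,2211
1,2023-07-22,474
1,2023-07-23,375
1,2023-07-24,438
1,2023-07-25,509
1,2023-07-26,361
1,2023-07-27,497
2,2023-07-22,112
2,2023-07-23,28
2,2023-07-24,46
2,2023-07-25,58
2,2023-07-26,46
2,2023-07-27,71
3,2023-07-22,50
3,2023-07-23,17
3,2023-07-24,23
3,2023-07-25,13
3,2023-07-26,10
3,2023-07-27,25
4,2023-07-22,12
4,2023-07-23,8
4,2023-07-24,12
4,2023-07-25,2
4,2023-07-26,6
4,2023-07-27,22
5,2023-07-22,1
5,2023-07-23,3
5,2023-07-24,1
5,2023-07-25,1
5,2023-07-26,2
5,2023-07-27,16
6,2023-07-22,6
6,2023-07-24,1
6,2023-07-25,1
6,2023-07-26,1
6,2023-07-27,9
7,2023-07-22,2
7,2023-07-25,2
7,2023-07-26,1
7,2023-07-27,10
8,2023-07-22,3
8,2023-07-27,2
9,2023-07-26,1
9,2023-07-27,3
10,2023-07-22,1
10,2023-07-25,1
10,2023-07-27,1
11,2023-07-23,2
11,2023-07-25,1
11,2023-07-27,1
12,2023-07-27,1
13,2023-07-27,1
14,2023-07-27,3
15,2023-07-22,1
15,2023-07-25,1
15,2023-07-26,1
15,2023-07-27,2
16,2023-07-24,1
16,2023-07-27,1
17,2023-07-22,2
17,2023-07-26,1
27,2023-07-26,1
28,2023-07-24,1
34,2023-07-27,1
35,2023-07-26,1
39,2023-07-26,1
64,2023-07-26,1
67,2023-07-26,2
69,2023-07-23,1
75,2023-07-25,1
97,2023-07-26,1
98,2023-07-26,1
99,2023-07-25,1
99,2023-07-26,2
99,2023-07-27,1
100,2023-07-22,1
100,2023-07-26,6
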