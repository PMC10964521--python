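genotype,sts,rank
1,-2.973,109
2,0.839,77
3,0.778,78
4,2.643,59
5,3.850,45
6,-1.702,100
7,1.486,71
8,5.687,25
9,-1.557,99
10,3.933,44
11,-0.143,90
12,11.291,6
13,-2.270,105
14,0.484,82
15,8.137,15
16,7.456,17
17,-2.608,106
18,-2.012,104
19,-0.225,91
20,5.173,30
21,2.369,62
22,7.220,19
23,0.879,76
24,1.025,75
25,-4.912,113
26,-2.823,107
27,2.512,60
28,-0.792,92
29,-1.924,102
30,6.103,22
31,4.397,39
32,7.746,16
33,6.233,20
34,4.341,40
35,8.337,13
36,2.759,57
37,-1.370,98
38,3.753,46
39,0.062,88
40,0.538,81
41,-1.936,103
42,4.104,41
43,3.001,52
44,4.894,33
45,2.957,53
46,3.021,51
47,4.041,42
48,2.673,58
49,0.272,83
50,-1.762,101
51,-4.678,112
52,5.381,28
53,2.237,65
54,5.375,29
55,-1.200,96
56,-4.499,110
57,6.011,23
58,1.382,73
59,4.405,38
60,-1.354,97
61,8.948,11
62,15.207,4
63,3.360,50
64,2.868,55
65,6.106,21
66,7.448,18
67,-2.954,108
68,-0.909,95
69,3.404,49
70,4.974,32
71,0.268,84
72,-6.041,114
73,10.174,9
74,10.359,8
75,2.939,54
76,5.498,27
77,4.820,35
78,9.987,10
79,4.872,34
80,2.194,66
81,2.445,61
82,4.446,37
83,3.982,43
84,8.334,14
85,10.931,7
86,17.793,2
87,8.475,12
88,17.819,1
89,4.779,36
90,0.110,87
91,0.547,80
92,3.642,47
93,1.396,72
94,2.762,56
95,1.716,68
96,-0.854,93
97,17.434,3
98,1.570,70
99,1.613,69
100,1.252,74
101,5.573,26
102,-0.868,94
103,-4.675,111
104,-0.101,89
105,1.850,67
106,0.209,85
107,2.274,63
108,4.995,31
109,2.259,64
110,5.798,24
111,3.571,48
112,0.577,79
113,13.467,5
114,0.141,86
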