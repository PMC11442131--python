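r,g,b
12,8,64
12,9,67
13,10,69
13,11,72
14,11,74
14,12,77
15,13,79
15,14,82
15,15,84
16,16,87
16,17,89
17,18,92
17,18,94
18,19,97
18,20,99
19,21,102
19,22,104
19,23,107
20,24,109
20,25,112
21,25,115
21,26,117
22,27,120
22,28,122
22,29,125
23,30,127
23,31,130
24,32,132
24,32,135
25,33,137
25,34,140
26,35,142
26,36,145
26,37,147
27,38,150
27,39,152
28,39,155
28,40,158
29,41,160
29,42,163
29,43,165
30,44,168
30,45,170
31,45,173
31,46,175
32,47,178
32,48,180
32,50,180
31,52,179
31,54,179
31,55,178
30,57,178
30,59,178
30,61,177
29,63,177
29,64,176
29,66,176
29,68,176
28,70,175
28,72,175
28,73,174
27,75,174
27,77,174
27,79,173
26,81,173
26,82,173
26,84,172
25,86,172
25,88,171
25,90,171
24,91,171
24,93,170
24,95,170
23,97,169
23,99,169
23,100,169
23,102,168
22,104,168
22,106,167
22,108,167
21,110,167
21,111,166
21,113,166
20,115,165
20,117,165
20,119,165
19,120,164
19,122,164
19,124,163
18,126,163
18,128,163
18,129,162
18,131,162
17,133,162
17,135,161
17,137,161
16,138,160
16,140,160
17,141,158
17,142,157
17,144,155
18,145,154
18,146,152
19,147,150
19,148,149
20,150,147
20,151,146
21,152,144
21,153,143
22,154,141
22,155,139
23,157,138
23,158,136
24,159,135
24,160,133
25,161,132
25,162,130
25,164,128
26,165,127
26,166,125
27,167,124
27,168,122
28,170,121
28,171,119
29,172,117
29,173,116
30,174,114
30,175,113
31,177,111
31,178,110
32,179,108
32,180,107
33,181,105
33,182,103
33,184,102
34,185,100
34,186,99
35,187,97
35,188,96
36,190,94
36,191,92
37,192,91
37,193,89
38,194,88
38,195,86
39,197,85
39,198,83
40,199,81
40,200,80
44,200,79
47,201,79
51,201,78
54,201,78
57,201,77
61,202,77
64,202,76
68,202,75
71,203,75
75,203,74
78,203,74
81,203,73
85,204,73
88,204,72
92,204,71
95,205,71
99,205,70
102,205,70
105,205,69
109,206,69
112,206,68
116,206,67
119,207,67
122,207,66
126,207,66
129,207,65
133,208,65
136,208,64
140,208,63
143,209,63
146,209,62
150,209,62
153,209,61
157,210,61
160,210,60
164,210,59
167,211,59
170,211,58
174,211,58
177,211,57
181,212,57
184,212,56
188,212,55
191,213,55
194,213,54
198,213,54
201,213,53
205,214,53
208,214,52
211,214,51
215,215,51
218,215,50
222,215,50
225,215,49
229,216,49
232,216,48
232,217,52
233,217,56
233,218,59
234,219,63
234,219,67
235,220,71
235,221,74
236,221,78
236,222,82
237,223,86
237,223,89
237,224,93
238,225,97
238,225,101
239,226,104
239,227,108
240,227,112
240,228,116
241,229,120
241,229,123
241,230,127
242,231,131
242,231,135
243,232,138
243,233,142
244,233,146
244,234,150
245,235,153
245,235,157
246,236,161
246,237,165
246,237,168
247,238,172
247,239,176
248,239,180
248,240,184
249,241,187
249,241,191
250,242,195
250,243,199
250,243,202
251,244,206
251,245,210
252,245,214
252,246,217
253,247,221
253,247,225
254,248,229
254,249,232
255,249,236
255,250,240
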