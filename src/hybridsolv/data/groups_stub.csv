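compound_id,groups
2,
3,
4,
5,
6,
7,
10,
11,
13,
15,
17,
19,
20,
21,
24,
26,
27,
33,
37,
42,
44,
45,
46,
47,
48,
49,
50,
55,
56,
58,
59,
60,
61,
63,
65,
67,
68,
69,
70,
71,
72,
74,
75,
80,
81,
82,
83,
84,
85,
86,
88,
90,
92,
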