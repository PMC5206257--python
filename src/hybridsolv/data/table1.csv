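compound_id,dg_water,se_water,dg_chex,se_chex,logd_pred,se_pred,logd_exp,err_exp
2,-55.2,0.1,-63.8,0.1,1.51,0.02,1.40,0.30
3,-47.9,0.1,-55.3,0.2,1.29,0.03,1.90,0.10
4,-55.7,0.1,-70.5,0.1,2.60,0.03,2.20,0.30
5,-73.7,0.2,-74.1,0.1,0.07,0.04,-0.86,0.09
6,-55.8,0.1,-50.5,0.1,-0.93,0.03,-1.02,0.09
7,-57.3,0.3,-69.3,0.2,2.11,0.06,1.40,0.30
10,-82.9,0.1,-58.8,0.2,-4.23,0.03,-1.70,0.40
11,-66.9,0.1,-63.2,0.1,-0.65,0.02,-2.96,0.08
13,-99.8,0.1,-89.4,0.1,-1.83,0.02,-1.50,0.40
15,-77.4,0.2,-59.3,0.1,-3.17,0.04,-2.20,0.30
17,-55.7,0.3,-77.6,0.1,3.85,0.06,2.50,0.30
19,-79.7,0.1,-76.4,0.1,-0.58,0.03,1.20,0.40
20,-79.5,1.9,-63.9,0.2,-2.74,0.33,1.60,0.30
21,-49.4,0.1,-62.2,0.1,2.26,0.02,1.20,0.30
24,-84.8,0.2,-85.1,0.2,0.05,0.04,1.00,0.40
26,-76.4,0.5,-52.5,0.2,-4.19,0.09,-2.60,0.10
27,-87.8,0.1,-57.3,0.1,-5.36,0.03,-1.87,0.07
33,-56.8,0.2,-73.6,0.2,2.95,0.04,1.80,0.20
37,-67.9,0.4,-52.3,0.2,-2.74,0.08,-1.50,0.10
42,-98.3,0.1,-69.9,0.2,-4.98,0.03,-1.10,0.30
44,-76.0,0.1,-81.3,0.1,0.93,0.02,1.00,0.40
45,-62.4,0.1,-50.6,0.1,-2.07,0.02,-2.10,0.20
46,-72.3,0.1,-71.3,0.1,-0.19,0.03,0.20,0.30
47,-65.5,0.1,-71.0,0.2,0.96,0.04,-0.40,0.30
48,-85.3,0.1,-80.2,0.1,-0.89,0.02,0.90,0.40
49,-53.5,0.1,-53.9,0.0,0.08,0.02,1.30,0.10
50,-65.3,0.1,-59.8,0.1,-0.96,0.02,-3.20,0.60
55,-53.3,0.1,-46.6,0.1,-1.17,0.02,-1.50,0.10
56,-59.4,0.1,-60.3,0.1,0.16,0.03,-2.50,0.10
58,-49.9,0.1,-54.7,0.1,0.84,0.02,0.80,0.10
59,-61.2,0.1,-43.5,0.1,-3.12,0.03,-1.30,0.30
60,-90.7,0.1,-56.2,0.1,-6.05,0.03,-3.90,0.20
61,-39.4,0.2,-51.7,0.1,2.15,0.04,-1.45,0.09
63,-71.2,0.4,-59.2,0.1,-2.10,0.07,-3.00,0.40
65,-140.5,0.2,-143.4,0.2,0.50,0.04,0.70,0.20
67,-50.3,1.0,-59.6,0.4,1.63,0.19,-1.30,0.30
68,-57.1,0.3,-73.2,0.2,2.83,0.07,1.40,0.30
69,-82.2,0.2,-81.9,0.3,-0.06,0.06,-1.30,0.30
70,-32.1,0.1,-62.4,0.2,5.31,0.03,1.60,0.30
71,-68.0,0.2,-66.3,0.1,-0.29,0.04,-0.10,0.50
72,-32.2,0.1,-57.1,0.1,4.36,0.03,0.60,0.30
74,-132.8,0.2,-75.8,0.2,-10.00,0.05,-1.90,0.30
75,-51.6,0.5,-66.1,0.3,2.56,0.11,-2.80,0.30
80,-71.1,0.1,-58.9,0.1,-2.14,0.02,-2.20,0.20
81,-80.1,1.4,-66.5,0.7,-2.39,0.28,-2.20,0.30
82,-37.5,0.3,-77.0,0.2,6.94,0.06,2.50,0.40
83,-165.1,1.9,-162.2,0.6,-0.50,0.35,-1.90,0.40
84,-67.4,0.9,-79.2,0.6,2.08,0.19,0.00,0.20
85,-83.8,0.1,-60.3,0.0,-4.12,0.02,-2.20,0.40
86,-58.1,0.6,-84.8,0.4,4.68,0.13,0.70,0.20
88,-64.2,0.2,-62.1,0.2,-0.36,0.05,-1.90,0.30
90,-53.8,0.1,-75.4,0.2,3.78,0.04,0.80,0.20
92,-107.3,2.1,-117.1,1.0,1.71,0.41,-0.40,0.30
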