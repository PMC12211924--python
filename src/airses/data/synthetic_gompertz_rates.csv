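age,sex,rate
50,female,2.54285426e-03
51,female,2.79627220e-03
52,female,3.07494549e-03
53,female,3.38139104e-03
54,female,3.71837660e-03
55,female,4.08894575e-03
56,female,4.49644540e-03
57,female,4.94455600e-03
58,female,5.43732480e-03
59,female,5.97920236e-03
60,female,6.57508282e-03
61,female,7.23034805e-03
62,female,7.95091626e-03
63,female,8.74329547e-03
64,female,9.61464228e-03
65,female,1.05728265e-02
66,female,1.16265023e-02
67,female,1.27851862e-02
68,female,1.40593432e-02
69,female,1.54604813e-02
70,female,1.70012552e-02
71,female,1.86955808e-02
72,female,2.05587610e-02
73,female,2.26076235e-02
74,female,2.48606734e-02
75,female,2.73382597e-02
76,female,3.00627593e-02
77,female,3.30587795e-02
78,female,3.63533796e-02
79,female,3.99763158e-02
80,female,4.39603097e-02
81,female,4.83413438e-02
82,female,5.31589868e-02
83,female,5.84567506e-02
84,female,6.42824834e-02
85,female,7.06888021e-02
86,female,7.77335672e-02
87,female,8.54804055e-02
88,female,9.39992849e-02
89,female,1.03367146e-01
90,female,1.13668597e-01
91,female,1.24996680e-01
92,female,1.37453706e-01
93,female,1.51152185e-01
94,female,1.66215838e-01
95,female,1.82780718e-01
96,female,2.00996436e-01
97,female,2.21027510e-01
98,female,2.43054859e-01
99,female,2.67277428e-01
100,female,2.93913990e-01
50,male,4.16103424e-03
51,male,4.57571815e-03
52,male,5.03172898e-03
53,male,5.53318533e-03
54,male,6.08461625e-03
55,male,6.69100214e-03
56,male,7.35781975e-03
57,male,8.09109164e-03
58,male,8.89744057e-03
59,male,9.78414932e-03
60,male,1.07592264e-02
61,male,1.18314786e-02
62,male,1.30105902e-02
63,male,1.43072108e-02
64,male,1.57330510e-02
65,male,1.73009889e-02
66,male,1.90251856e-02
67,male,2.09212138e-02
68,male,2.30061980e-02
69,male,2.52989694e-02
70,male,2.78202357e-02
71,male,3.05927686e-02
72,male,3.36416089e-02
73,male,3.69942931e-02
74,male,4.06811020e-02
75,male,4.47353340e-02
76,male,4.91936062e-02
77,male,5.40961847e-02
78,male,5.94873485e-02
79,male,6.54157895e-02
80,male,7.19350522e-02
81,male,7.91040172e-02
82,male,8.69874330e-02
83,male,9.56565009e-02
84,male,1.05189518e-01
85,male,1.15672585e-01
86,male,1.27200383e-01
87,male,1.39877027e-01
88,male,1.53817012e-01
89,male,1.69146239e-01
90,male,1.86003159e-01
91,male,2.04540021e-01
92,male,2.24924246e-01
93,male,2.47339938e-01
94,male,2.71989554e-01
95,male,2.99095721e-01
96,male,3.28903258e-01
97,male,3.61681380e-01
98,male,3.97726133e-01
99,male,4.37363064e-01
100,male,4.80950166e-01
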