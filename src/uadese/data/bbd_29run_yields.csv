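run_id,water_content,ultrasonic_power,extraction_temperature,extraction_time,water_content_nat,ultrasonic_power_nat,extraction_temperature_nat,extraction_time_nat,yield_mg_per_g
1,-1,-1,0,0,20,100,50,30,1.189
2,1,-1,0,0,40,100,50,30,1.148
3,-1,1,0,0,20,300,50,30,1.124
4,1,1,0,0,40,300,50,30,1.121
5,0,0,-1,-1,30,200,45,20,1.107
6,0,0,1,-1,30,200,55,20,1.189
7,0,0,-1,1,30,200,45,40,1.134
8,0,0,1,1,30,200,55,40,1.204
9,-1,0,0,-1,20,200,50,20,1.239
10,1,0,0,-1,40,200,50,20,1.056
11,-1,0,0,1,20,200,50,40,1.164
12,1,0,0,1,40,200,50,40,1.205
13,0,-1,-1,0,30,100,45,30,1.208
14,0,1,-1,0,30,300,45,30,1.123
15,0,-1,1,0,30,100,55,30,1.189
16,0,1,1,0,30,300,55,30,1.254
17,-1,0,-1,0,20,200,45,30,1.088
18,1,0,-1,0,40,200,45,30,1.009
19,-1,0,1,0,20,200,55,30,1.167
20,1,0,1,0,40,200,55,30,1.098
21,0,-1,0,-1,30,100,50,20,1.172
22,0,1,0,-1,30,300,50,20,1.229
23,0,-1,0,1,30,100,50,40,1.278
24,0,1,0,1,30,300,50,40,1.248
25,0,0,0,0,30,200,50,30,1.31
26,0,0,0,0,30,200,50,30,1.38
27,0,0,0,0,30,200,50,30,1.299
28,0,0,0,0,30,200,50,30,1.302
29,0,0,0,0,30,200,50,30,1.301
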