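channel	source	detector	separation_cm	hemisphere	region
1	F7	FC3	3.0	left	broca
2	F7	C5	3.0	left	broca
3	FC5	FC3	3.0	left	broca
4	FC5	C5	3.0	left	broca
5	FT7	C5	3.0	left	broca
6	FT7	TP7	3.0	left	adjacent
7	T7	C5	3.0	left	adjacent
8	T7	TP7	3.0	left	adjacent
9	CP5	C5	3.0	left	adjacent
10	CP5	CP3	3.0	left	wernicke
11	CP5	TP7	3.0	left	wernicke
12	P7	TP7	3.0	left	wernicke
13	P7	P5	3.0	left	wernicke
14	F8	FC4	3.0	right	broca
15	F8	C6	3.0	right	broca
16	FC6	FC4	3.0	right	broca
17	FC6	C6	3.0	right	broca
18	FT8	C6	3.0	right	broca
19	FT8	TP8	3.0	right	adjacent
20	T8	C6	3.0	right	adjacent
21	T8	TP8	3.0	right	adjacent
22	CP6	C6	3.0	right	adjacent
23	CP6	CP4	3.0	right	wernicke
24	CP6	TP8	3.0	right	wernicke
25	P8	TP8	3.0	right	wernicke
26	P8	P6	3.0	right	wernicke
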