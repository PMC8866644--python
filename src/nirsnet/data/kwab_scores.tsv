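patient	session	stim_site	hotspot_channel	AQ	LQ	speech	repeat	reading	comprehension	naming	writing
1	T0	broca	5	52.0	53.9	13	16	59	142	43	45
1	T1	broca	5	56.8	58.4
1	T2	broca	5	55.6	57.8
2	T0	adjacent	8	27.6	25.0	7	16	45	89	7	18
2	T1	adjacent	8	34.4	33.1
2	T2	adjacent	8	38.4	35.4
3	T0	wernicke	10	97.6	98.4	19.5	100	100	197	94	99
3	T1	wernicke	10	99.0	99.5
3	T2	wernicke	10	99.0	99.5
4	T0	wernicke	10	47.8	40.1	8	60	29	96	51	28
4	T1	wernicke	10	56.4	51.7
4	T2	wernicke	10	55.6	50.1
5	T0	wernicke	11	63.6	57.1	14.5	22	54	146	78	36
5	T1	wernicke	11	67.0	61.6
5	T2	wernicke	11	59.0	54.3
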