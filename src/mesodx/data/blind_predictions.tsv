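sample	class_1	score_1	class_2	score_2	histological_class
1	MPM	28.07	MPM	41.57	MPM
2	MPM	93.44	MPM	115.4	MPM
3	MH	62.97	MH	160.5	MH
4	MPM	7.54	MPM	11.83	MPM
5	MH	8.6	MH	12.47	MH
6	MPM	12	MPM	16.75	MPM
7	MPM	29.05	MPM	37.11	MPM
8	MH	30.97	MH	34.39	MH
9	MH	52.15	MH	51.91	MH
10	MPM	8.37	MPM	15.91	MPM
11	MPM	11.42	MPM	14.06	MPM
12	MPM	10.12	MPM	16.3	MPM
13	MPM	10.46	MPM	15.82	MPM
14	MH	10.99	MH	13.84	MH
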