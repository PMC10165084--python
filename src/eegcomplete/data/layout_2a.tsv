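id	name	x_cm	y_cm
1	Fz	0.0	5.0
2	FC3	-5.0	2.5
3	FC1	-2.5	2.5
4	FCz	0.0	2.5
5	FC2	2.5	2.5
6	FC4	5.0	2.5
7	C5	-7.5	0.0
8	C3	-5.0	0.0
9	C1	-2.5	0.0
10	Cz	0.0	0.0
11	C2	2.5	0.0
12	C4	5.0	0.0
13	C6	7.5	0.0
14	CP3	-5.0	-2.5
15	CP1	-2.5	-2.5
16	CPz	0.0	-2.5
17	CP2	2.5	-2.5
18	CP4	5.0	-2.5
19	P1	-2.5	-5.0
20	Pz	0.0	-5.0
21	P2	2.5	-5.0
22	POz	0.0	-7.5
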