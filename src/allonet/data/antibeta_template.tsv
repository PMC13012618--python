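resoffset	atom	x_nm	y_nm	z_nm
0	N	-0.1200	0.0500	0.0000
0	CA	0.0000	0.0000	0.0300
0	CB	0.0000	-0.1100	0.1100
0	C	0.1200	0.0500	0.0000
0	O	0.1400	0.1700	-0.0200
1	N	0.2300	0.0500	0.0000
1	CA	0.3500	0.0000	0.0300
1	CB	0.3500	-0.1100	0.1100
1	C	0.4700	0.0500	0.0000
1	O	0.4900	0.1700	-0.0200
2	N	0.5800	0.0500	0.0000
2	CA	0.7000	0.0000	0.0300
2	CB	0.7000	-0.1100	0.1100
2	C	0.8200	0.0500	0.0000
2	O	0.8400	0.1700	-0.0200
3	N	0.8200	0.4300	0.0000
3	CA	0.7000	0.4800	0.0300
3	CB	0.7000	0.5900	0.1100
3	C	0.5800	0.4300	0.0000
3	O	0.5600	0.3100	-0.0200
4	N	0.4700	0.4300	0.0000
4	CA	0.3500	0.4800	0.0300
4	CB	0.3500	0.5900	0.1100
4	C	0.2300	0.4300	0.0000
4	O	0.2100	0.3100	-0.0200
5	N	0.1200	0.4300	0.0000
5	CA	0.0000	0.4800	0.0300
5	CB	0.0000	0.5900	0.1100
5	C	-0.1200	0.4300	0.0000
5	O	-0.1400	0.3100	-0.0200
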