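left	right	dG
0	1	3.80
0	2	2.80
0	3	3.20
0	4	3.60
1	0	3.80
1	1	1.00
1	2	2.10
1	3	2.90
1	4	3.60
2	0	2.80
2	1	2.10
2	2	1.70
2	3	2.40
2	4	3.20
3	0	3.20
3	1	2.90
3	2	2.40
3	3	2.00
3	4	2.80
4	0	3.60
4	1	3.60
4	2	3.20
4	3	2.80
4	4	2.30
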