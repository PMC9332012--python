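bin	count
-7 or less	0
-6	0
-5	0
-4	0
-3	0
-2	1
-1	4
0	5
1	11
2	11
3	10
4	16
5	17
6	6
7 or more	14
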