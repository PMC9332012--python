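bin	count
-7 or less	1
-6	1
-5	3
-4	12
-3	18
-2	63
-1	71
0	61
1	21
2	7
3	0
4	1
5	0
6	0
7 or more	0
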