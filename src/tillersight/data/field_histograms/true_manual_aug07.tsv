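bin	count
-7 or less	1
-6	3
-5	0
-4	6
-3	22
-2	21
-1	17
0	22
1	13
2	4
3	7
4	0
5	0
6	0
7 or more	0
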