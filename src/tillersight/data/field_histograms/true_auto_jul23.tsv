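bin	count
-7 or less	0
-6	0
-5	0
-4	1
-3	1
-2	9
-1	3
0	8
1	17
2	12
3	10
4	11
5	6
6	5
7 or more	12
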