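bin	count
-7 or less	0
-6	1
-5	1
-4	2
-3	11
-2	29
-1	19
0	18
1	9
2	5
3	0
4	0
5	0
6	0
7 or more	0
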