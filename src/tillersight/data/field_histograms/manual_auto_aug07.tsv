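bin	count
-7 or less	3
-6	1
-5	3
-4	2
-3	2
-2	4
-1	9
0	11
1	16
2	23
3	10
4	13
5	6
6	3
7 or more	10
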