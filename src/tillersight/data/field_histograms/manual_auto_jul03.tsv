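bin	count
-7 or less	0
-6	0
-5	0
-4	1
-3	5
-2	9
-1	12
0	26
1	49
2	40
3	47
4	38
5	16
6	10
7 or more	6
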