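bin	count
-7 or less	1
-6	1
-5	1
-4	6
-3	16
-2	16
-1	25
0	40
1	41
2	38
3	33
4	21
5	12
6	3
7 or more	5
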