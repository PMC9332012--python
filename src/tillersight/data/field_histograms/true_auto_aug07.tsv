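bin	count
-7 or less	3
-6	3
-5	4
-4	5
-3	5
-2	10
-1	11
0	15
1	15
2	15
3	5
4	7
5	8
6	5
7 or more	5
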