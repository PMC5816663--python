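precursor_id	product_id
1	2
2	3
2	4
4	5
5	6
4	7
7	8
2	9
9	10
10	11
9	12
12	13
13	14
12	15
15	16
7	17
17	18
2	19
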