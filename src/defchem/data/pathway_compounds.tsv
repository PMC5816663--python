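id	name	class
1	Phenol	phenol
2	Hydroquinone	hydroquinone
3	1,4-Benzoquinone	benzoquinone
4	2-Methoxyhydroquinone	hydroquinone
5	2-Methoxy-1,4-benzoquinone	benzoquinone
6	2-Methoxy-3-hydroxy-1,4-benzoquinone	benzoquinone
7	2,3-Dimethoxyhydroquinone	hydroquinone
8	2,3-Dimethoxy-1,4-benzoquinone	benzoquinone
9	2-Methylhydroquinone	hydroquinone
10	2-Methyl-1,4-benzoquinone	benzoquinone
11	2-Methyl-3-hydroxy-1,4-benzoquinone	benzoquinone
12	2-Methoxy-3-methylhydroquinone	hydroquinone
13	2-Methoxy-3-methyl-1,4-benzoquinone	benzoquinone
14	2-Methoxy-3-methyl-5-hydroxy-1,4-benzoquinone	benzoquinone
15	2-Methoxy-3,6-dimethylhydroquinone	hydroquinone
16	2-Methoxy-3,6-dimethyl-1,4-benzoquinone	benzoquinone
17	2,3-dimethoxy-5-methylhydroquinone	hydroquinone
18	2,3-dimethoxy-5-methyl-1,4-benzoquinone	benzoquinone
19	2-Ethyl-1,4-benzoquinone	benzoquinone
20	Naphthoquinone	benzoquinone
21	Benzoil cyanide	other
22	alpha-terpinene	other
23	Polyzonimine	other
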