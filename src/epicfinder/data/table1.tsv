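# PCR screening matrix: intron x genus, categories P/I/A/(blank=null)/na
# merge: 2,22
intron	Paracentrotus	Amphipholis	Echinocardium	Corella	Perophora	Styela	Abatus	Sterechinus	Macoma	Cerastoderma	Corallium	Paramuricea
1	I	P	P	A	P	P	I	P	I	P	P	
2	P	P	P	P	P	P	P	P	I	I	I	na
3		I	I	I					I		na	na
4											na	na
5	P	P	P	P	P	P	P	I	I	P	I	I
6											na	na
7		I									na	na
8							I	I	I	I	na	na
9	P	P		I	I	P	I	I	I	A	I	na
11	I	I	I	I	P	I			I	I	na	na
12	I		P	I		I	I	I	I	I	na	na
13							I				na	na
14		I									na	na
15	I	I	I	I	P	I	P	A	I	P	I	I
17											na	na
19	P				P		A	A	A	A	na	na
21	P	I	P	I	P	I	P	P	I	I	I	na
22	P	I	P	I			A	I	A	A	I	na
24											na	na
25	I	I	I	P	P	P	I	P	P	I	P	na
26									I		na	na
29	P	I	P	I		I	P	P	P		I	na
30	P	A	I	A	A	I	P	A	A	A	na	na
34	P					A	P	I	I	P	na	na
35											na	na
36		I		I	P	P	P	I	I	P		
37		I	P		P	P	I			P	A	I
38	A	I			I	P					I	I
39	P		P									
40												
41	I						I				na	na
42		I	I	I		I						
43		I	P	P	P	I	P		P		P	I
44	A	I	A	P	A						na	na
45				I	P	I			I	I	I	
46	I	I			I		P				P	I
47		I			A	A					I	I
48		P	I	I	I	P	P	P	I	I		
49											A	
50	P	P	I	P	P	I	I	P	P	I	I	P
51	P	I		I	P	I	P	P	I	P	P	
52	P										A	na
53	P	I	P				P	P	I	P	P	P
54	P	P	P	A	I	I	I	I			I	I
55			P				I				A	
56				P	I	I				P	A	P
57	I						P	P				P
58									I		na	na
ATPsaJ		I	I	I	I	P			P		na	na
ATPSai2		I	I				I	P		P	na	na
EF3	A	I		I	P	A	I	I	A	A	na	na
EF4	I	I	I	A	I	I	I	P	P	P	na	na
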