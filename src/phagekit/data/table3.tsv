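# Genome annotation of Burkholderia phage JC1 (GenBank OM283127, 61,182 bp):
# 76 predicted protein-coding genes. Printed coordinate dialect: 1-based
# inclusive; minus-strand genes are written with start > end.
gene	start	end	strand	length_aa	product
1	1660	5	-	551	serine recombinase
2	2081	1794	-	95	hypothetical protein
3	2493	2146	-	115	hypothetical protein
4	2867	2490	-	125	hypothetical protein
5	3895	2864	-	343	RecT-like protein
6	4976	3945	-	343	nuclease/RecB-like protein
7	5697	5104	-	197	repressor
8	5821	6165	+	114	transcriptional regulator
9	6335	6685	+	116	hypothetical protein
10	6737	7546	+	269	virion-associated protein
11	7642	8142	+	166	single stranded DNA binding protein
12	8151	8369	+	72	hypothetical protein
13	8366	8842	+	158	hypothetical protein
14	8839	9201	+	120	hypothetical protein
15	9352	9807	+	151	hypothetical protein
16	10127	9801	-	108	hypothetical protein
17	10389	10132	-	85	hypothetical protein
18	10744	10974	+	76	hypothetical protein
19	10971	11357	+	128	helicase
20	11354	12178	+	274	replication initiator protein
21	12175	12975	+	266	DnaC-like protein
22	13057	13182	+	41	hypothetical protein
23	13337	13765	+	142	hypothetical protein
24	13771	14106	+	111	hypothetical protein
25	14166	14609	+	147	hypothetical protein
26	14652	15041	+	129	hypothetical protein
27	15044	15325	+	93	hypothetical protein
28	15364	16602	+	412	hypothetical protein
29	17017	16658	-	119	hypothetical protein
30	17210	18010	+	266	terminase small subunit
31	18090	18338	+	82	hypothetical protein
32	18389	18517	+	42	hypothetical protein
33	18562	18840	+	92	hypothetical protein
34	18872	19066	+	64	hypothetical protein
35	19059	20366	+	435	hypothetical protein
36	20356	20766	+	136	hypothetical protein
37	20851	21033	+	60	hypothetical protein
38	21030	21416	+	128	hypothetical protein
39	21413	21700	+	95	hypothetical protein
40	21697	22035	+	112	hypothetical protein
41	22172	22582	+	136	DUF2778 domain-containing protein
42	22579	22860	+	93	hypothetical protein
43	22948	24549	+	533	terminase large subunit
44	24560	24991	+	143	hypothetical protein
45	25013	27310	+	765	portal protein
46	27318	28340	+	340	virion-associated protein
47	28367	28561	+	64	carbon storage regulator
48	28660	29754	+	364	major capsid protein
49	29821	30288	+	155	virion-associated protein
50	30346	30942	+	198	hypothetical protein
51	30946	31593	+	215	virion-associated protein
52	31590	32219	+	209	virion-associated protein
53	32229	32648	+	139	virion-associated protein
54	32653	33528	+	291	hypothetical protein
55	33510	33788	+	92	virion-associated protein
56	33790	34740	+	316	tail fiber protein
57	34744	35814	+	356	tail fiber protein
58	35811	36323	+	170	hypothetical protein
59	36484	37530	+	348	tail fiber protein
60	37532	38221	+	229	hypothetical protein
61	38276	40018	+	580	head closure protein
62	40020	40373	+	117	hypothetical protein
63	40424	40864	+	146	acetyltransferase
64	40857	41855	+	332	virion-associated protein
65	41867	42589	+	240	phosphoadenosine phosphosulfate reductase
66	42589	42888	+	99	hypothetical protein
67	42905	43495	+	196	virion-associated protein
68	43506	45038	+	510	virion-associated protein
69	45123	58670	+	4515	DarB-like antirestriction protein
70	58940	58701	-	79	hypothetical protein
71	59287	58991	-	98	hypothetical protein
72	59443	59790	+	115	LydA-like holin
73	59787	60059	+	90	holin
74	60056	60634	+	192	lysozyme
75	60631	61140	+	169	Rz
76	60866	61087	+	73	Rz1
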