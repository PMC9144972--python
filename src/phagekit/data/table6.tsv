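# Proteins identified by whole-lane mass spectrometry of CsCl-purified JC1
# virions. unique_peptides counts unique medium-to-high-quality peptides.
protein	score	coverage	unique_peptides	putative_function
gp48	298.44	56.04	27	Major capsid protein
gp69	88.92	15.61	51	DarB-like antirestriction protein
gp49	82.92	50.32	6	Virion-associated protein
gp64	45.94	45.18	9	Hypothetical protein
gp53	30.63	58.99	5	Virion-associated protein
gp68	27.46	17.06	9	Hypothetical Protein
gp45	25.85	22.22	14	Portal protein
gp56	22.88	41.14	7	Tail fiber protein
gp52	19.47	46.41	8	Hypothetical protein
gp61	16.01	11.21	6	Virion-associated phage protein
gp10	13.4	21.56	5	Hypothetical protein
gp55	13.16	48.91	4	Virion-associated phage protein
gp51	12.97	25.58	5	Hypothetical protein
gp67	9.35	42.86	7	Virion-associated phage protein
gp46	4.14	13.82	4	Hypothetical protein
gp47	2.61	18.75	1	Carbon storage regulator
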