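# Host-range panel of Burkholderia phage JC1 on 85 Bcc clinical and environmental isolates.
# score: numeric = efficiency of plating relative to isolation host Van1;
#        + / ++ / +++ = clearing without plaques at 1e10 / 1e9 / 1e8 PFU/mL;
#        ND = no lysis detected.
species	strain	score	source
B. cepacia	ATCC 25416	ND	Onion (type strain)
B. cepacia	ATCC 17759	ND	Soil, Trinidad
B. cepacia	CEP509/LMG 18821	6.7e-7	CF patient, Australia
B. cepacia	CEP521	7.3e-7	CF patient, Canada
B. multivorans	ATCC 17616	+++	Soil, USA
B. multivorans	C3430	ND	CF patient, Canada
B. multivorans	C1576, LMG 16660	ND	CF-e patient, UK
B. multivorans	C5274	8.0e-6	CF patient, Canada
B. multivorans	C5393	ND	CF patient, Canada
B. multivorans	C5568	++	CF patient, Canada
B. multivorans	JC1	++	CF patient, Canada
B. multivorans	LMG 13010	++	CF patient, Belgium (type strain)
B. multivorans	M1512	ND	CF patient, Canada
B. multivorans	M1865	ND	CF patient, Canada
B. multivorans	R810	ND	CF patient, Canada
B. multivorans	R1159	ND	CF patient, Canada
B. cenocepacia	AU1054	0.93	CF patient
B. cenocepacia	715j	ND	CF patient, USA
B. cenocepacia	BS1	++	CF patient, Canada
B. cenocepacia	BS2	++	CF patient, Canada
B. cenocepacia	BS3	++	CF patient, Canada
B. cenocepacia	C1257	++	CF-e patient, USA
B. cenocepacia	C4455	++	CF-e patient, Canada
B. cenocepacia	C5424	0.25	CF-e patient, Canada
B. cenocepacia	C6433	ND	CF-e patient, Canada
B. cenocepacia	C8963	0.3	CF patient, Canada
B. cenocepacia	C9343	ND	CF patient, Canada
B. cenocepacia	CEP511	++	CF-e patient, Australia
B. cenocepacia	CEP0868	0.002	CF patient, Argentina
B. cenocepacia	D1	ND	Soil, USA
B. cenocepacia	HI2424	ND	Soil, USA
B. cenocepacia	J2315	0.14	CF-e patient, UK
B. cenocepacia	K56-2	+++	CF-e patient, Canada
B. cenocepacia	K63-3	ND	CF-e patient, Canada
B. cenocepacia	LMG 19240	ND	Wheat soil, Australia
B. cenocepacia	MCO-3	ND	Maize soil, USA
B. cenocepacia	PC184	0.19	CF-e patient, USA
B. cenocepacia	R161	+	CF patient, Canada
B. cenocepacia	R452	+	CF patient, Canada
B. cenocepacia	R750	0.9	CF patient, Canada
B. cenocepacia	R1284	0.022	CF patient, Canada
B. cenocepacia	R1285	0.6	CF patient, Canada
B. cenocepacia	R1314	++	CF patient, Canada
B. cenocepacia	R1434	0.86	CF patient, Canada
B. cenocepacia	R1619	++	CF patient, Canada
B. cenocepacia	R1882	0.53	CF patient, Canada
B. cenocepacia	R1883	0.47	CF patient, Canada
B. cenocepacia	R1884	1	CF patient, Canada
B. cenocepacia	R2314	0.73	CF patient, Canada
B. cenocepacia	RK1b	0.31	CF patient, Canada
B. cenocepacia	S11528	0.8	CF patient, Canada
B. cenocepacia	Van1	1	CF patient, Canada (isolation host)
B. stabilis	LMG 14294	+	CF patient, Belgium
B. stabilis	C7322/LMG 18870	6.0e-4	CF patient, Canada
B. stabilis	R450	ND	CF patient, Canada
B. stabilis	R2140	+	CF patient, Canada
B. stabilis	R2339	ND	CF patient, Canada
B. vietnamiensis	DBO1	ND	Soil, USA
B. vietnamiensis	LMG 10929	ND	Rice, Vietnam (type strain)
B. vietnamiensis	PC259/LMG 18835	+	CF patient, USA
B. vietnamiensis	G4	ND	Soil, USA
B. dolosa	AU0158	++	CF patient, USA
B. dolosa	CEP021	+	CF patient, USA
B. dolosa	E12	8.6e-5	CF patient, UK
B. dolosa	STM1441	ND	Soil, Senegal
B. ambifaria	AMMD	ND	Soil, USA (type strain)
B. ambifaria	ATCC 53266	2.3e-5	Soil, USA
B. ambifaria	CEP996	0.31	CF patient, Australia
B. ambifaria	M53	ND	Soil, USA
B. anthina	AU1293	0.8	CF patient, USA
B. anthina	C1765	4.3e-3	CF patient, UK
B. anthina	J2552	ND	Soil, UK
B. anthina	W92	ND	Soil, USA (type strain)
B. pyrrocinia	ATCC 15958	ND	Soil, Japan
B. pyrrocinia	ATCC 39277	ND	Soil, USA
B. pyrrocinia	BC011	ND	Water, USA
B. pyrrocinia	C1469	ND	CF patient, UK
Bcc Group K	CEP0964	ND	CF patient, Canada
Bcc Group K	CEP1056	++	CF patient, Canada
Bcc Group K	R445	3.1e-5	CF patient, Canada
B. lata	383	ND	Soil, Trinidad
Burkholderia sp.	JS150	1	Soil, USA
Pandoraea sp.	R1717	ND	CF patient, Canada
Ralstonia pickettii	ATCC 27511	0.7	Patient isolate, USA
Ralstonia pickettii	YH105	ND	Soil, USA
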