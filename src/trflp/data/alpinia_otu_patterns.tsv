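otu_id	hha_trf	msp_trf	taxon_name	rank	identity_pct	flag
1	389	-	Marasmius	genus	95
2	85	101	Basidiomycota	phylum	98
3	90	97	Trechisporales	order	94
4	101	85	Basidiomycota	phylum	100
5	174	142	Penicillium	genus	99
6	153	161	Fusarium	genus	99
7	170	131	Colletotrichum	genus	99
8	139	527	Fusarium	genus	99
9	325	148	Pestalotiopsis	genus	99
10	170	142	Colletotrichum	genus	100
11	241	170	Basidiomycota	phylum	99
12	317	142	Colletotrichum	genus	99
13	540	170	Sebacinales	order	99
14	222	170	Sebacina	genus	92
15	139	161	Exserohilum	genus	99
16	359	126	Mycoleptodiscus	genus	99
17	161	94	Mycoleptodiscus	genus	99
18	160	131	Colletotrichum	genus	99
19	148	323	unresolved	unresolved	-	#
20	382	151	Basidiomycota	phylum	97
21	122	142	unresolved	unresolved	-	#
22	345	126	Scopulariopsis	genus	97
23	337	142	Meyerozyma	genus	99
24	80	395	Ascomycota	phylum	79
25	139	131	Exserohilum	genus	99
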