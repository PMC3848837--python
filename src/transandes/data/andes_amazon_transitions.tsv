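class	group	taxa	highest_elevation_m	polarity	age	source
Mammals	vesper mice (Sigmodontinae)	Calomys	5000	Andes->Amazon	16.3% in cyt-b (8.2 Ma)	B21
Mammals	olingos (Procyonidae)	Bassaricyon	2750	Andes->Amazon	3.5	B93
Birds	antshrikes (Thamnophilidae)	Thamnophilus	2300	Andes->Amazon	< 1 Ma	B14
Birds	tanagers (Thraupidae)	Tangara	3500	Andes->Amazon	7.5	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Andes->Amazon	7.5	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Andes->Amazon	5	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Andes->Amazon	3	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Andes->Amazon	3	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Andes->Amazon	3	B94;B95
Birds	spinetails (Furnariidae)	Cranioleuca	4400	Andes->Amazon	1	B94
Birds	spinetails (Furnariidae)	Cranioleuca	4400	Andes->Amazon	0.5	B94
Birds	miners (Furnariidae)	Geositta	4900	Andes->Amazon	10	B94
Birds	miners (Furnariidae)	Geositta	4900	Andes->Amazon	9	B94
Birds	miners (Furnariidae)	Geositta	4900	Andes->Amazon	5	B94
Birds	ovenbirds (Furnariidae)	Cinclodes	5200	Andes->Amazon	0.5	B94
Birds	greenfinches (Fringillidae)	Carduelis	4600	Andes->Amazon	1	B94
Birds	greenfinches (Fringillidae)	Carduelis	4600	Andes->Amazon	0.5	B94
Birds	parrots (Psittacidae)	Pionus (menstruus group)	3000	Andes->Amazon	5.6	B15
Amphibians	poison frogs (Dendrobatidae)	Dendrobates	1958	Andes->Amazon	21.1	B20
Amphibians	poison frogs (Dendrobatidae)	Dendrobates	1958	Andes->Amazon	6.5	B20
Amphibians	poison frogs (Dendrobatidae)	Dendrobates	1958	Andes->Amazon	2.4	B20
Amphibians	poison frogs (Dendrobatidae)	Hyloxalus	3500	Andes->Amazon	7.4	B20
Amphibians	poison frogs (Dendrobatidae)	Hyloxalus	3500	Andes->Amazon	5.6	B20
Amphibians	poison frogs (Dendrobatidae)	Hyloxalus	3500	Andes->Amazon	5.1	B20
Amphibians	poison frogs (Dendrobatidae)	Hyloxalus	3500	Andes->Amazon	4.7	B20
Amphibians	poison frogs (Dendrobatidae)	Hyloxalus	3500	Andes->Amazon	1.6	B20
Amphibians	poison frogs (Dendrobatidae)	Ameerega	2020	Andes->Amazon	7.2	B20;B96
Amphibians	poison frogs (Dendrobatidae)	Ameerega	2020	Andes->Amazon	6.7	B20;B96
Amphibians	poison frogs (Dendrobatidae)	Ameerega	2020	Andes->Amazon	6.1	B20;B96
Amphibians	poison frogs (Dendrobatidae)	Ameerega	2020	Andes->Amazon	3.1	B20;B96
Amphibians	salamanders (Plethodontidae)	Bolitoglossa	2000	Andes->Amazon	23.6	B97
Insects	butterflies (Nymphalidae)	Ithomia	2400	Andes->Amazon	10	B98
Insects	butterflies (Nymphalidae)	Ithomia	2400	Andes->Amazon	7	B98
Insects	butterflies (Nymphalidae)	Napeogenes	2700	Andes->Amazon	11	B98
Insects	butterflies (Nymphalidae)	Napeogenes	2700	Andes->Amazon	2	B98
Mammals	spiny tree-rats (Echimyidae)	Mesomys	1581	Amazon->Andes	2.8-1.2	source-study
Mammals	bamboo rats (Echimyidae)	bamboo rat clade	3200	Amazon->Andes	9.0-4.2	source-study
Mammals	mouse opossums (Didelphidae)	Marmosa (Micoureus)	1634	Amazon->Andes	12.7% in cyt-b (6.4 Ma)	B19;B99;B100
Mammals	night monkeys (Nyctipithecidae)	Aotus	3200	Amazon->Andes	< 1 Ma	B101
Mammals	howler monkeys (Atelidae)	Alouatta	3200	Amazon->Andes	2.5	B101
Mammals	howler monkeys (Atelidae)	Alouatta	3200	Amazon->Andes	2.5	B101
Birds	antshrikes (Thamnophilidae)	Thamnophilus	2300	Amazon->Andes	5.5-3	B14
Birds	antshrikes (Thamnophilidae)	Thamnophilus	2300	Amazon->Andes	3.6-1.6	B14
Birds	flycatchers (Tyrannidae)	Leptopogon	2700	Amazon->Andes	9-6	B12
Birds	flycatchers (Tyrannidae)	Leptopogon	2700	Amazon->Andes	6-3	B12
Birds	flycatchers (Tyrannidae)	Myarchus	3000	Amazon->Andes	3	B94
Birds	parrots (Psittacidae)	Pionus (sordidus group)	3000	Amazon->Andes	3.0	B15
Birds	parrots (Psittacidae)	Amazona	3300	Amazon->Andes	2	B94
Birds	parrots (Psittacidae)	Amazona	3300	Amazon->Andes	1	B94
Birds	tanagers (Thraupidae)	Tangara	3500	Amazon->Andes	7	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Amazon->Andes	4	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Amazon->Andes	3.5	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Amazon->Andes	3	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Amazon->Andes	3	B94;B95
Birds	tanagers (Thraupidae)	Tangara	3500	Amazon->Andes	1	B94;B95
Birds	trogons (Trogonidae)	Trogon	3400	Amazon->Andes	7	B94
Birds	trogons (Trogonidae)	Trogon	3400	Amazon->Andes	6	B94
Birds	potoos (Nyctibiidae)	Nyctibius	2800	Amazon->Andes	7.5	B94
Birds	blackbirds (Icteridae)	blackbird clade	3200	Amazon->Andes	5	B94
Birds	blackbirds (Icteridae)	blackbird clade	3200	Amazon->Andes	4	B94
Birds	blackbirds (Icteridae)	blackbird clade	3200	Amazon->Andes	3.5	B94
Birds	oropendolas (Icteridae)	Psarocolius and relatives	3300	Amazon->Andes	5.5	B94
Birds	oropendolas (Icteridae)	Psarocolius and relatives	3300	Amazon->Andes	2	B94
Birds	oropendolas (Icteridae)	Psarocolius and relatives	3300	Amazon->Andes	1	B94
Birds	orioles (Icteridae)	Icterus	2800	Amazon->Andes	7	B94
Birds	orioles (Icteridae)	Icterus	2800	Amazon->Andes	5.5	B94
Birds	orioles (Icteridae)	Icterus	2800	Amazon->Andes	1	B94
Birds	woodcreepers (Furnariidae)	Xiphorhynchus	2400	Amazon->Andes	5	B94
Birds	woodcreepers (Furnariidae)	Xiphorhynchus	2400	Amazon->Andes	3.5	B94
Birds	woodcreepers (Furnariidae)	Dendrocincla	2500	Amazon->Andes	7	B94
Birds	woodpeckers (Picidae)	Veniliornis	3600	Amazon->Andes	4	B94
Birds	woodpeckers (Picidae)	Veniliornis	3600	Amazon->Andes	3.5	B94
Birds	woodpeckers (Picidae)	Veniliornis	3600	Amazon->Andes	1	B94
Birds	woodpeckers (Picidae)	Veniliornis	3600	Amazon->Andes	1	B94
Birds	swallows (Hirundininae)	Neotropical swallow clade	4400	Amazon->Andes	11	B94
Birds	swallows (Hirundininae)	Neotropical swallow clade	4400	Amazon->Andes	6	B94
Birds	swallows (Hirundininae)	Neotropical swallow clade	4400	Amazon->Andes	3.5	B94
Birds	swallows (Hirundininae)	Neotropical swallow clade	4400	Amazon->Andes	2	B94
Amphibians	poison frogs (Dendrobatidae)	Dendrobates	1958	Amazon->Andes	4.4	B20
Amphibians	poison frogs (Dendrobatidae)	Ameerega	2020	Amazon->Andes	2.4	B20
Amphibians	poison frogs (Dendrobatidae)	Allobates	2630	Amazon->Andes	21.8	B20
Amphibians	poison frogs (Dendrobatidae)	Allobates	2630	Amazon->Andes	15.2	B20
Amphibians	poison frogs (Dendrobatidae)	Allobates	2630	Amazon->Andes	10.6	B20
Amphibians	poison frogs (Dendrobatidae)	Allobates	2630	Amazon->Andes	1.2	B20
Amphibians	poison frogs (Dendrobatidae)	Allobates	2630	Amazon->Andes	0.8	B20
Insects	butterflies (Riodinidae)	Ithomiola	2100	Amazon->Andes	not dated	B13
Insects	butterflies (Riodinidae)	Ithomiola	2100	Amazon->Andes	not dated	B13
Insects	butterflies (Nymphalidae)	Napeogenes	2700	Amazon->Andes	5.5	B98
Insects	butterflies (Nymphalidae)	Napeogenes	2700	Amazon->Andes	4.5	B98
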