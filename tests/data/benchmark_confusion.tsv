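genus	TP	TN	FP	FN
Leuconostoc	4	1198	0	0
Ruegeria	3	1197	2	0
Helicobacter	6	1194	2	0
Paenibacillus	6	1192	4	0
Cutibacterium	25	1173	4	0
Moraxella	7	1190	5	0
Synechococcus	29	1166	7	0
Lactococcus	47	1145	9	1
Streptococcus	39	1152	10	1
Mycolicibacterium	320	847	33	2
Staphylococcus	37	1155	8	2
Arthrobacter	45	1150	4	3
Rhodococcus	11	1189	1	1
Microbacterium	21	1171	8	2
Bacillus	32	1156	11	3
Gordonia	55	1135	5	7
Flavobacterium	6	1194	1	1
Acinetobacter	9	1188	3	2
Pseudomonas	46	1129	16	11
Aeromonas	7	1190	3	2
Corynebacterium	3	1194	4	1
Caulobacter	3	1193	5	1
Proteus	2	1199	0	1
Mannheimia	2	1197	2	1
Streptomyces	23	1164	3	12
Escherichia	82	1044	31	45
Enterococcus	6	1189	3	4
Listeria	4	1195	0	3
Erwinia	5	1192	1	4
Campylobacter	8	1180	7	7
Salmonella	20	1147	13	22
Lactobacillus	5	1185	6	6
Clostridioides	2	1197	0	3
Clostridium	2	1195	2	3
Yersinia	2	1192	5	3
Vibrio	13	1163	6	20
Rhizobium	1	1198	1	2
Klebsiella	5	1176	8	13
Xanthomonas	1	1194	3	4
Cronobacter	1	1193	4	4
Pectobacterium	1	1194	2	5
Pseudoalteromonas	1	1192	4	5
Brucella	1	1194	1	6
Ralstonia	1	1193	2	6
Cellulophaga	1	1193	2	6
Burkholderia	1	1191	4	6
Shigella	1	1184	7	10
Stenotrophomonas	0	1199	0	3
Citrobacter	0	1196	1	5
Mycobacterium	0	1196	4	2
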