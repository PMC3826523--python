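# Curated visual opsin gene locations across vertebrate genome assemblies
# (GRCh37, NCBIM37, MonDom5, WASHUC2, AnoCar2.0, JGI_4.2, LatCha1, LepOcu1,
# Zv9, BROADS1, MEDAKA1, TETRAODON8).  Positions published at Mb precision
# are stored as 0-based point anchors (end = start + 1); the zebrafish
# exo-rhodopsin scaffold position is given in bp.  Chicken LWS/SWS1/SWS2 and
# the pouched-lamprey genes are omitted (no assembly placement).
species	locus_id	family	subtype	chromosome	start	end	strand	has_introns
human	human_OPN1LW	opsin	LWS	X	153410000	153410001	?	true
human	human_OPN1MW2	opsin	LWS	X	153490000	153490001	?	true
human	human_OPN1MW	opsin	LWS	X	153450000	153450001	?	true
human	human_RHO	opsin	RH1	3	129250000	129250001	?	true
human	human_OPN1SW	opsin	SWS1	7	128410000	128410001	?	true
mouse	mouse_Opn1mw	opsin	LWS	X	71370000	71370001	?	true
mouse	mouse_Rho	opsin	RH1	6	115880000	115880001	?	true
mouse	mouse_Opn1sw	opsin	SWS1	6	29330000	29330001	?	true
opossum	opossum_LWS	opsin	LWS	X	14660000	14660001	?	true
opossum	opossum_RH1	opsin	RH1	6	246610000	246610001	?	true
opossum	opossum_SWS1	opsin	SWS1	8	188610000	188610001	?	true
chicken	chicken_RH1	opsin	RH1	12	20160000	20160001	?	true
chicken	chicken_RH2	opsin	RH2	26	4380000	4380001	?	true
anole	anole_LWS	opsin	LWS	2	88660000	88660001	?	true
anole	anole_RH1	opsin	RH1	GL343273.1	640000	640001	?	true
anole	anole_RH2	opsin	RH2	4	122810000	122810001	?	true
anole	anole_SWS1	opsin	SWS1	GL343828.1	110000	110001	?	true
anole	anole_SWS2	opsin	SWS2	2	88630000	88630001	?	true
frog	frog_opn1lw	opsin	LWS	GL172911.1	210000	210001	?	true
frog	frog_rho	opsin	RH1	GL172832.1	1640000	1640001	?	true
frog	frog_opn1sw	opsin	SWS1	GL173116.1	610000	610001	?	true
frog	frog_SWS2	opsin	SWS2	GL172911.1	220000	220001	?	true
coelacanth	coelacanth_RH1	opsin	RH1	JH126975.1	800000	800001	?	true
coelacanth	coelacanth_RH2	opsin	RH2	JH126819.1	1630000	1630001	?	true
coelacanth	coelacanth_SWS2	opsin	SWS2	JH127263.1	540000	540001	?	true
gar	gar_LWS	opsin	LWS	LG1	2610000	2610001	?	true
gar	gar_RH1-1	opsin	RH1	LG5	40450000	40450001	?	true
gar	gar_RH1-2	opsin	RH1	LG5	23740000	23740001	?	false
gar	gar_RH2	opsin	RH2	LG3	36550000	36550001	?	true
gar	gar_SWS1-1	opsin	SWS1	LG8	10390000	10390001	?	true
gar	gar_SWS1-2	opsin	SWS1	LG8	10400000	10400001	?	true
gar	gar_SWS2	opsin	SWS2	LG1	2620000	2620001	?	true
zebrafish	zebrafish_opn1lw1	opsin	LWS	11	26410000	26410001	?	true
zebrafish	zebrafish_opn1lw2	opsin	LWS	11	26410000	26410001	?	true
zebrafish	zebrafish_exorh	opsin	RH1	Zv9_NA986	130	131	?	true
zebrafish	zebrafish_rho	opsin	RH1	8	55710000	55710001	?	false
zebrafish	zebrafish_rhol	opsin	RH1	11	19520000	19520001	?	false
zebrafish	zebrafish_opn1mw1	opsin	RH2	6	41110000	41110001	?	true
zebrafish	zebrafish_opn1mw2	opsin	RH2	6	41120000	41120001	?	true
zebrafish	zebrafish_opn1mw3	opsin	RH2	6	41120000	41120001	?	true
zebrafish	zebrafish_opn1mw4	opsin	RH2	6	41130000	41130001	?	true
zebrafish	zebrafish_opn1sw1	opsin	SWS1	4	12640000	12640001	?	true
zebrafish	zebrafish_opn1sw2	opsin	SWS2	11	26410000	26410001	?	true
stickleback	stickleback_LWS	opsin	LWS	XVII	10630000	10630001	?	true
stickleback	stickleback_RH1-1	opsin	RH1	XII	1180000	1180001	?	true
stickleback	stickleback_RH1-2	opsin	RH1	XII	810000	810001	?	false
stickleback	stickleback_RH2-1	opsin	RH2	scaffold_27	4150000	4150001	?	true
stickleback	stickleback_RH2-2	opsin	RH2	scaffold_27	4160000	4160001	?	true
stickleback	stickleback_SWS1	opsin	SWS1	scaffold_90	460000	460001	?	true
stickleback	stickleback_SWS2	opsin	SWS2	XVII	10620000	10620001	?	true
medaka	medaka_LWS-1	opsin	LWS	5	27020000	27020001	?	true
medaka	medaka_LWS-2	opsin	LWS	5	27010000	27010001	?	true
medaka	medaka_RH1-1	opsin	RH1	7	17430000	17430001	?	true
medaka	medaka_RH1-2	opsin	RH1	7	17100000	17100001	?	false
medaka	medaka_RH2-1	opsin	RH2	ultracontig_62	1610000	1610001	?	true
medaka	medaka_RH2-2	opsin	RH2	ultracontig_62	1620000	1620001	?	true
medaka	medaka_RH2-3	opsin	RH2	ultracontig_62	1620000	1620001	?	true
medaka	medaka_SWS1	opsin	SWS1	scaffold_1021	40000	40001	?	true
medaka	medaka_SWS2-1	opsin	SWS2	5	27010000	27010001	?	true
medaka	medaka_SWS2-2	opsin	SWS2	5	27000000	27000001	?	true
pufferfish	pufferfish_LWS	opsin	LWS	11	10120000	10120001	?	true
pufferfish	pufferfish_RH1-1	opsin	RH1	9	6680000	6680001	?	true
pufferfish	pufferfish_RH1-2	opsin	RH1	9	6480000	6480001	?	false
pufferfish	pufferfish_RH2	opsin	RH2	11	5970000	5970001	?	true
pufferfish	pufferfish_SWS2	opsin	SWS2	11	10120000	10120001	?	true
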