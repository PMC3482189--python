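class	ssu_species	ssu_accession	lsu_species	lsu_accession	group
Sordariomycetes	Chaetomium globosum	AY545725	Chaetomium globosum	AAFU01000611	ingroup
Sordariomycetes	Diaporthe sp.	AB245446	Diaporthe angelicae	AY196781	ingroup
Sordariomycetes	Halosarpheia retorquens	AF050486	Halosarpheia japonica	HQ009884	ingroup
Sordariomycetes	Hypocrea rufa	AY489694	Hypocrea jecorina	AF510497	ingroup
Sordariomycetes	Meliola niessleana	AF021794	Meliola variaseta	EF094840	ingroup
Sordariomycetes	Microascus cirrosus	M89994	Microascus trigonosporus	DQ470958	ingroup
Sordariomycetes	Neurospora crassa	X04971	Neurospora crassa	FJ360521	ingroup
Sordariomycetes	Sordaria fimicola	X69851	Sordaria fimicola	AY545728	ingroup
Sordariomycetes	Xylaria carpophila	Z49785	Xylaria hypoxylon	AY544648	ingroup
Leotiomycetes	Ascocoryne solitaria	DQ002904	Ascocoryne sarcoides	FJ176886	ingroup
Leotiomycetes	Bulgaria inquinans	AJ224362	Bulgaria inquinans	DQ470960	ingroup
Leotiomycetes	Caespitotheca forestalis	AB193465	Caespitotheca forestalis	AB193467	ingroup
Leotiomycetes	Coccomyces dentatus	AY544701	Coccomyces strobi	DQ470975	ingroup
Leotiomycetes	Erysiphe mori	AB033484	Erysiphe pisi	CACM01000006	ingroup
Leotiomycetes	Leotia lubrica	AY544687	Leotia lubrica	AY544644	ingroup
Leotiomycetes	Sclerotinia sclerotiorum	AY187065	Sclerotinia sclerotiorum	DQ470965	ingroup
Leotiomycetes	Thelebolus ellipsoideus	DQ067574	Thelebolus ellipsoideus	FJ176895	ingroup
Geoglossomycetes	Geoglossum nigritum	AF113716	Geoglossum nigritum	AY544650	ingroup
Geoglossomycetes	Sarcoleotia globosa	AY789298	Sarcoleotia globosa	AY789428	ingroup
Geoglossomycetes	Trichoglossum hirsutum	AY544697	Trichoglossum hirsutum	AY544653	ingroup
Eurotiomycetes	Aspergillus penicillioides	AB002060	Aspergillus protuberus	FJ176897	ingroup
Eurotiomycetes	Capronia coronata	AJ232939	Capronia mansonii	AY004338	ingroup
Eurotiomycetes	Catapyrenium lachneum	AF412410	Catapyrenium cinereum	EF643747	ingroup
Eurotiomycetes	Elaphomyces maculatus	U45440	Elaphomyces guangdongensis	HM357248	ingroup
Eurotiomycetes	Eupenicillium crustaceum	D88324	Eupenicillium ochrosalmoneum	EF626957	ingroup
Eurotiomycetes	Eurotium rubrum	U00970	Eurotium sp.	FR848827	ingroup
Eurotiomycetes	Monascus purpureus	DQ782881	Monascus purpureus	DQ782908	ingroup
Eurotiomycetes	Onygena equina	U45442	Onygena corvina	FJ358287	ingroup
Eurotiomycetes	Trichophyton rubrum	X58570	Trichophyton equinum	ABWI01001612	ingroup
Lecanoromycetes	Cladonia rangiferina	AF184753	Cladonia stipitata	DQ973026	ingroup
Lecanoromycetes	Lecanora dispersa	L37734	Lecanora contractula	DQ986746	ingroup
Lecanoromycetes	Parmelia saxatilis	AF117985	Parmelia saxatilis	AY300849	ingroup
Lecanoromycetes	Physcia aipolia	AF241542	Physcia aipolia	DQ782904	ingroup
Lecanoromycetes	Usnea florida	AF117988	Usnea strigosa	DQ973033	ingroup
Dothideomycetes	Botryosphaeria ribis	U42477	Botryosphaeria stevensii	DQ678064	ingroup
Dothideomycetes	Cochliobolus sativus	U42479	Cochliobolus sativus	DQ678045	ingroup
Dothideomycetes	Dothidea sambuci	AY544722	Dothidea insculpta	DQ247802	ingroup
Dothideomycetes	Leptosphaeria maculans	DQ470993	Leptosphaeria maculans	DQ470946	ingroup
Dothideomycetes	Mycosphaerella mycopappi	U43463	Mycosphaerella pneumatophorae	FJ176856	ingroup
Dothideomycetes	Myriangium duriaei	AY016347	Myriangium duriaei	DQ678059	ingroup
Dothideomycetes	Pleospora herbarum	U05201	Pleospora sp.	EF177848	ingroup
Dothideomycetes	Rhytidhysteron rufulum	AF201452	Rhytidhysteron rufulum	GU397353	ingroup
Pezizomycetes	Acervus epispartius	DQ787814	Acervus epispartius	DQ220305	ingroup
Pezizomycetes	Chorioactis geaster	AF104340	Chorioactis geaster	AY307945	ingroup
Pezizomycetes	Galiella rufa	AF004948	Galiella rufa	FJ176869	ingroup
Pezizomycetes	Morchella esculenta	U42642	Morchella cf. elata	AY544665	ingroup
Pezizomycetes	Otidea leporina	DQ248955	Otidea leporina	DQ220386	ingroup
Pezizomycetes	Phillipsia domingensis	AF006315	Phillipsia olivacea	AY945843	ingroup
Pezizomycetes	Pseudopithyella minuscula	AF006317	Pseudopithyella minuscula	AY544658	ingroup
Pezizomycetes	Pyronema domesticum	U53385	Pyronema domesticum	DQ247805	ingroup
Pezizomycetes	Sarcoscypha coccinea	AY544691	Sarcoscypha coccinea	FJ176859	ingroup
Pezizomycetes	Scutellinia korfiana	DQ787829	Scutellinia scutellata	DQ247806	ingroup
Pezizomycetes	Tuber gibbosum	U42663	Tuber gibbosum	FJ176877	ingroup
Pezizomycetes	Wolfina aurantiopsis	AF104664	Wolfina aurantiopsis	AY945859	ingroup
Orbiliomycetes	Orbilia auricolor	DQ471001	Orbilia auricolor	DQ470953	ingroup
Orbiliomycetes	Orbilia delicatula	U72603	Orbilia delicatula	AY261178	ingroup
Neolectomycetes	Neolecta vitellina	DQ471037	Neolecta vitellina	DQ470985	ingroup
Neolectomycetes	Neolecta irregularis	DQ842040	Neolecta irregularis	DQ470986	ingroup
Saccharomycetes	Candida glabrata	AY218893	Candida albicans	DM167147	ingroup
Saccharomycetes	Saccharomyces cerevisiae	U53879	Saccharomyces cerevisiae	U53879	ingroup
Taphrinomycetes	Protomyces inouyei	D11377	Protomyces inouyei	AY548294	ingroup
Taphrinomycetes	Taphrina deformans	U00971	Taphrina deformans	DQ470973	ingroup
Schizosaccharomycetes	Schizosaccharomyces pombe	X54866	Schizosaccharomyces japonicus	AATM01000140	ingroup
Chytridiomycota	Chytridium polysiphoniae	AY032608	Chytridium sp.	DQ273831	outgroup
Zygomycota	Mucor racemosus	AJ271061	Mucor racemosus	M26190	outgroup
Zygomycota	Rhizopus oryzae	AB250174	Rhizopus oryzae	AACW02000152	outgroup
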