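# Morphological character codings for the 66-taxon table (taxon = SSU species).
# Class-level assignments with documented exceptions: within Leotiomycetes,
# Caespitotheca and Erysiphe bear sealed/ostiolar ascomata rather than exposed hymenia.
# Dothideomycetes are coded 'Ostiolar or sealed' at class level although a subset of
# the class is apothecial; that subset is not enumerated taxon-by-taxon in the source
# descriptions, so the class-level coding is retained rather than guessed per taxon.
# Outgroup taxa (non-Ascomycota) lack asci: ascus state is missing ('?'); ascoma Absent.
taxon	class	ascus_dehiscence	ascoma_shape
Chaetomium globosum	Sordariomycetes	Inoperculate	Ostiolar or sealed
Diaporthe sp.	Sordariomycetes	Inoperculate	Ostiolar or sealed
Halosarpheia retorquens	Sordariomycetes	Inoperculate	Ostiolar or sealed
Hypocrea rufa	Sordariomycetes	Inoperculate	Ostiolar or sealed
Meliola niessleana	Sordariomycetes	Inoperculate	Ostiolar or sealed
Microascus cirrosus	Sordariomycetes	Inoperculate	Ostiolar or sealed
Neurospora crassa	Sordariomycetes	Inoperculate	Ostiolar or sealed
Sordaria fimicola	Sordariomycetes	Inoperculate	Ostiolar or sealed
Xylaria carpophila	Sordariomycetes	Inoperculate	Ostiolar or sealed
Ascocoryne solitaria	Leotiomycetes	Inoperculate	With exposed hymenium
Bulgaria inquinans	Leotiomycetes	Inoperculate	With exposed hymenium
Caespitotheca forestalis	Leotiomycetes	Inoperculate	Ostiolar or sealed
Coccomyces dentatus	Leotiomycetes	Inoperculate	With exposed hymenium
Erysiphe mori	Leotiomycetes	Inoperculate	Ostiolar or sealed
Leotia lubrica	Leotiomycetes	Inoperculate	With exposed hymenium
Sclerotinia sclerotiorum	Leotiomycetes	Inoperculate	With exposed hymenium
Thelebolus ellipsoideus	Leotiomycetes	Inoperculate	With exposed hymenium
Geoglossum nigritum	Geoglossomycetes	Inoperculate	With exposed hymenium
Sarcoleotia globosa	Geoglossomycetes	Inoperculate	With exposed hymenium
Trichoglossum hirsutum	Geoglossomycetes	Inoperculate	With exposed hymenium
Aspergillus penicillioides	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Capronia coronata	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Catapyrenium lachneum	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Elaphomyces maculatus	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Eupenicillium crustaceum	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Eurotium rubrum	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Monascus purpureus	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Onygena equina	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Trichophyton rubrum	Eurotiomycetes	Schizosaccharomyces-Saccharomyces	Ostiolar or sealed
Cladonia rangiferina	Lecanoromycetes	Bitunicate	With exposed hymenium
Lecanora dispersa	Lecanoromycetes	Bitunicate	With exposed hymenium
Parmelia saxatilis	Lecanoromycetes	Bitunicate	With exposed hymenium
Physcia aipolia	Lecanoromycetes	Bitunicate	With exposed hymenium
Usnea florida	Lecanoromycetes	Bitunicate	With exposed hymenium
Botryosphaeria ribis	Dothideomycetes	Bitunicate	Ostiolar or sealed
Cochliobolus sativus	Dothideomycetes	Bitunicate	Ostiolar or sealed
Dothidea sambuci	Dothideomycetes	Bitunicate	Ostiolar or sealed
Leptosphaeria maculans	Dothideomycetes	Bitunicate	Ostiolar or sealed
Mycosphaerella mycopappi	Dothideomycetes	Bitunicate	Ostiolar or sealed
Myriangium duriaei	Dothideomycetes	Bitunicate	Ostiolar or sealed
Pleospora herbarum	Dothideomycetes	Bitunicate	Ostiolar or sealed
Rhytidhysteron rufulum	Dothideomycetes	Bitunicate	Ostiolar or sealed
Acervus epispartius	Pezizomycetes	Operculate	With exposed hymenium
Chorioactis geaster	Pezizomycetes	Operculate	With exposed hymenium
Galiella rufa	Pezizomycetes	Operculate	With exposed hymenium
Morchella esculenta	Pezizomycetes	Operculate	With exposed hymenium
Otidea leporina	Pezizomycetes	Operculate	With exposed hymenium
Phillipsia domingensis	Pezizomycetes	Operculate	With exposed hymenium
Pseudopithyella minuscula	Pezizomycetes	Operculate	With exposed hymenium
Pyronema domesticum	Pezizomycetes	Operculate	With exposed hymenium
Sarcoscypha coccinea	Pezizomycetes	Operculate	With exposed hymenium
Scutellinia korfiana	Pezizomycetes	Operculate	With exposed hymenium
Tuber gibbosum	Pezizomycetes	Operculate	With exposed hymenium
Wolfina aurantiopsis	Pezizomycetes	Operculate	With exposed hymenium
Orbilia auricolor	Orbiliomycetes	Orbilia	With exposed hymenium
Orbilia delicatula	Orbiliomycetes	Orbilia	With exposed hymenium
Neolecta vitellina	Neolectomycetes	Taphrina-Neolecta	With exposed hymenium
Neolecta irregularis	Neolectomycetes	Taphrina-Neolecta	With exposed hymenium
Candida glabrata	Saccharomycetes	Schizosaccharomyces-Saccharomyces	Absent
Saccharomyces cerevisiae	Saccharomycetes	Schizosaccharomyces-Saccharomyces	Absent
Protomyces inouyei	Taphrinomycetes	Taphrina-Neolecta	Absent
Taphrina deformans	Taphrinomycetes	Taphrina-Neolecta	Absent
Schizosaccharomyces pombe	Schizosaccharomycetes	Schizosaccharomyces-Saccharomyces	Absent
Chytridium polysiphoniae	Chytridiomycota	?	Absent
Mucor racemosus	Zygomycota	?	Absent
Rhizopus oryzae	Zygomycota	?	Absent
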