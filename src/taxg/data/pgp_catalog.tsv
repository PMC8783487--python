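# Plant-growth-promoting gene catalog: trait<TAB>symbols (comma-sep)<TAB>product patterns (semicolon-sep, case-insensitive regex)
# Direct mechanisms: phosphate solubilization/regulation, auxin (IAA) pathway, ethylene modulation.
# Indirect mechanisms: lytic enzymes and antibiotic biosynthesis.
ppx-gppA	ppx-gppA,ppx,gppA	exopolyphosphatase;guanosine.*pentaphosphate phosphohydrolase;inorganic polyphosphate.*phosphatase
pstS	pstS	phosphate[- ]binding protein;phosphate ABC transporter.*substrate[- ]binding
senX3	senX3	sensor histidine kinase SenX3;two-component.*sensor.*SenX3
trpA	trpA	tryptophan synthase.*alpha
trpB	trpB	tryptophan synthase.*beta
trpD	trpD	anthranilate phosphoribosyl ?transferase
trpE	trpE	anthranilate synthase
trpF	trpF	phosphoribosylanthranilate isomerase;N-\(5'-phosphoribosyl\)anthranilate isomerase
pdxI	pdxI	pyridoxine 4-dehydrogenase
aad	aad	aryl[- ]alcohol dehydrogenase
acc	acc,acdS	1-aminocyclopropane-1-carboxylate deaminase;ACC deaminase;1-aminocylopropane-1-carboxylate ?deaminase
fabG	fabG	3-oxoacyl-\[acyl-carrier-protein\] reductase;3-oxoacyl-ACP reductase
bacC2	bacC2,bacC	bacitracin syntheta?se
hdhA	hdhA	7-alpha-hydroxysteroid dehydrogenase
auaJ	auaJ,lasC	epoxidase LasC;lasalocid.*epoxidase
tcmO	tcmO	tetracenomycin.*8-O-methyl ?transferase;8-O-methyltransferase.*tetracenomycin
chitinase	chiA,chiB,chiC	chitinase
glucoamylase	glaA	glucoamylase;glucan 1,4-alpha-glucosidase
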