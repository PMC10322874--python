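family	category	note
GH13	alpha_glucan	alpha-amylase / starch and pullulan backbone
GH77	alpha_glucan	4-alpha-glucanotransferase
GH15	alpha_glucan	glucoamylase
GH31	alpha_glucan	alpha-glucosidase
GH37	alpha_glucan	trehalase
GH57	alpha_glucan	alpha-amylase family
GH65	alpha_glucan	maltose phosphorylase
GH97	alpha_glucan	glucoamylase / alpha-glucosidase
CBM48	alpha_glucan	glycogen/starch-binding module
GH16	beta_glucan	endo-laminarinase (beta-1,3 backbone)
GH17	beta_glucan	endo-beta-1,3-glucanase
GH30	beta_glucan	removes beta-1,6 side-chain glucose of laminarin
GH1	beta_glucan	beta-glucosidase on oligo-beta-glucan
GH3	beta_glucan	beta-glucosidase on oligo-beta-glucan
GH5	beta_glucan	endo-glucanase also active on oligo-beta-glucan
GH23	N_glycan	lysozyme / peptidoglycan lytic transglycosylase
GH103	N_glycan	peptidoglycan lytic transglycosylase
GH73	N_glycan	peptidoglycan beta-N-acetylglucosaminidase
GH24	N_glycan	lysozyme
GH108	N_glycan	lysozyme
GH18	N_glycan	chitinase
GH20	N_glycan	beta-N-acetylglucosaminidase
GH109	N_glycan	N-acetylhexosaminidase on glycoconjugates
GH33	N_glycan	sialidase on glycoconjugates
AA10	N_glycan	lytic polysaccharide monooxygenase on crystalline chitin
GH43	cellulose_hemicellulose	beta-xylosidase / arabinofuranosidase
GH2	cellulose_hemicellulose	arabinosidase / beta-galactosidase
GH5	cellulose_hemicellulose	endo-beta-1,4-glucanase (cellulase) / xylanase
CE1	cellulose_hemicellulose	acetyl-xylan esterase
GH130	beta_mannoside	beta-1,4-mannooligosaccharide phosphorylase
GH26	beta_mannoside	beta-mannanase
AA2	lignin	peroxidase
AA3	lignin	GMC oxidoreductase assisting lignocellulose breakdown
AA6	lignin	1,4-benzoquinone reductase (Fenton-type lignin modification)
GH29	fucose_SP	alpha-L-fucosidase
GH95	fucose_SP	alpha-L-fucosidase
CBM47	fucose_SP	fucose-binding module
GH78	rhamnose_SP	alpha-L-rhamnosidase
GH106	rhamnose_SP	alpha-L-rhamnosidase
GH145	rhamnose_SP	rhamnogalacturonan hydrolase
CBM67	rhamnose_SP	rhamnose-binding module
PL1	pectin	pectate lyase
GH28	pectin	polygalacturonase
GH105	pectin	unsaturated glucuronyl/galacturonyl hydrolase
CE8	pectin	pectin methylesterase
CE12	pectin	pectin acetylesterase
PL6	alginate	alginate lyase
PL7	alginate	alginate lyase
PL17	alginate	oligo-alginate lyase
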