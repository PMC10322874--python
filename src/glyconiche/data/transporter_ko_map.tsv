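ko_id	class	note
K02025	ABC	ABC.MS.P multiple sugar transport system permease protein
K02026	ABC	ABC.MS.P1 multiple sugar transport system permease protein
K02027	ABC	ABC.MS.S multiple sugar transport system substrate-binding protein
K02056	ABC	ABC.SS.A simple sugar transport system ATP-binding protein
K02057	ABC	ABC.SS.P simple sugar transport system permease protein
K02058	ABC	ABC.SS.S simple sugar transport system substrate-binding protein
K10111	ABC	malK/mtlK/thuK multiple sugar transport system ATP-binding protein
K10191	ABC	lacK lactose/L-arabinose transport system ATP-binding protein
K10235	ABC	aglK alpha-glucoside transport system ATP-binding protein
K10560	ABC	rhaP rhamnose transport system permease protein
K10561	ABC	rhaQ rhamnose transport system permease protein
K17315	ABC	gtsA/glcE glucose/mannose transport system substrate-binding protein
K17316	ABC	gtsB/glcF glucose/mannose transport system permease protein
K17317	ABC	gtsC/glcG glucose/mannose transport system permease protein
K02429	MFS	fucP MFS transporter, FHS family, L-fucose permease
K02532	MFS	lacY MFS transporter, OHS family, lactose permease
K08138	MFS	xylE MFS transporter, SP family, xylose:H+ symporter
K02768	PTS	fruB PTS system, fructose-specific IIA component
K02769	PTS	fruA PTS system, fructose-specific IIB component
K02777	PTS	crr PTS system, sugar-specific IIA component
K11202	PTS	PTS system, fructose-specific IIB-like component
K03832	TonB	tonB periplasmic protein TonB
K21573	SusC	susC TonB-dependent starch-binding outer membrane protein SusC
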