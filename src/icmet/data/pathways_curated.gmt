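TCA cycle	curated mini-map	citrate	cis-aconitate	isocitrate	2-oxoglutarate	succinate	fumarate	malate	oxaloacetate
Tryptophan metabolism	curated mini-map	tryptophan	kynurenine	3-hydroxykynurenine	3-hydroxyanthranilate	2-aminomuconate	2-oxoadipate	kynurenate	quinolinate
Lysine degradation	curated mini-map	lysine	saccharopine	2-aminoadipate	2-oxoadipate	glutarate	glutaryl-carnitine
Pentose phosphate pathway	curated mini-map	glucose 6-phosphate	6-phosphogluconate	ribulose 5-phosphate	ribose 5-phosphate	xylulose 5-phosphate	sedoheptulose 7-phosphate	erythrose 4-phosphate	fructose 6-phosphate
Butanoate metabolism	curated mini-map	butanoate	acetoacetate	3-hydroxybutyrate	2-oxoglutarate	succinate	4-hydroxybutanoate
Glyoxylate and dicarboxylate metabolism	curated mini-map	glyoxylate	glycolate	oxalate	citrate	isocitrate	malate	glycerate
Glycolysis	curated mini-map	glucose 6-phosphate	fructose 6-phosphate	fructose 1,6-bisphosphate	glyceraldehyde 3-phosphate	3-phosphoglycerate	2-phosphoglycerate	phosphoenolpyruvate	pyruvate	lactate
Alanine, aspartate and glutamate metabolism	curated mini-map	aspartate	glutamate	glutamine	asparagine	2-oxoglutarate	oxaloacetate	N-acetylaspartate	N-acetylaspartylglutamate
Nicotinate and nicotinamide metabolism	curated mini-map	quinolinate	nicotinate	NAD	NADH	nicotinamide
Pyruvate metabolism	curated mini-map	pyruvate	lactate	malate	oxaloacetate	acetate	2-hydroxyglutarate
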