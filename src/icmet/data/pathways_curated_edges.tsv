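# pathway	node_a	node_b — undirected reaction adjacency (curated mini-map)
TCA cycle	citrate	cis-aconitate
TCA cycle	cis-aconitate	isocitrate
TCA cycle	isocitrate	2-oxoglutarate
TCA cycle	2-oxoglutarate	succinate
TCA cycle	succinate	fumarate
TCA cycle	fumarate	malate
TCA cycle	malate	oxaloacetate
TCA cycle	oxaloacetate	citrate
Tryptophan metabolism	tryptophan	kynurenine
Tryptophan metabolism	kynurenine	kynurenate
Tryptophan metabolism	kynurenine	3-hydroxykynurenine
Tryptophan metabolism	3-hydroxykynurenine	3-hydroxyanthranilate
Tryptophan metabolism	3-hydroxyanthranilate	quinolinate
Tryptophan metabolism	3-hydroxyanthranilate	2-aminomuconate
Tryptophan metabolism	2-aminomuconate	2-oxoadipate
Lysine degradation	lysine	saccharopine
Lysine degradation	saccharopine	2-aminoadipate
Lysine degradation	2-aminoadipate	2-oxoadipate
Lysine degradation	2-oxoadipate	glutarate
Lysine degradation	glutarate	glutaryl-carnitine
Pentose phosphate pathway	glucose 6-phosphate	6-phosphogluconate
Pentose phosphate pathway	6-phosphogluconate	ribulose 5-phosphate
Pentose phosphate pathway	ribulose 5-phosphate	ribose 5-phosphate
Pentose phosphate pathway	ribulose 5-phosphate	xylulose 5-phosphate
Pentose phosphate pathway	ribose 5-phosphate	sedoheptulose 7-phosphate
Pentose phosphate pathway	sedoheptulose 7-phosphate	erythrose 4-phosphate
Pentose phosphate pathway	erythrose 4-phosphate	fructose 6-phosphate
Butanoate metabolism	butanoate	acetoacetate
Butanoate metabolism	acetoacetate	3-hydroxybutyrate
Butanoate metabolism	butanoate	4-hydroxybutanoate
Butanoate metabolism	2-oxoglutarate	succinate
Butanoate metabolism	succinate	4-hydroxybutanoate
Glyoxylate and dicarboxylate metabolism	glyoxylate	glycolate
Glyoxylate and dicarboxylate metabolism	glyoxylate	oxalate
Glyoxylate and dicarboxylate metabolism	glyoxylate	glycerate
Glyoxylate and dicarboxylate metabolism	citrate	isocitrate
Glyoxylate and dicarboxylate metabolism	isocitrate	glyoxylate
Glyoxylate and dicarboxylate metabolism	glyoxylate	malate
Glycolysis	glucose 6-phosphate	fructose 6-phosphate
Glycolysis	fructose 6-phosphate	fructose 1,6-bisphosphate
Glycolysis	fructose 1,6-bisphosphate	glyceraldehyde 3-phosphate
Glycolysis	glyceraldehyde 3-phosphate	3-phosphoglycerate
Glycolysis	3-phosphoglycerate	2-phosphoglycerate
Glycolysis	2-phosphoglycerate	phosphoenolpyruvate
Glycolysis	phosphoenolpyruvate	pyruvate
Glycolysis	pyruvate	lactate
Alanine, aspartate and glutamate metabolism	aspartate	oxaloacetate
Alanine, aspartate and glutamate metabolism	aspartate	asparagine
Alanine, aspartate and glutamate metabolism	aspartate	N-acetylaspartate
Alanine, aspartate and glutamate metabolism	N-acetylaspartate	N-acetylaspartylglutamate
Alanine, aspartate and glutamate metabolism	glutamate	glutamine
Alanine, aspartate and glutamate metabolism	glutamate	2-oxoglutarate
Alanine, aspartate and glutamate metabolism	glutamate	N-acetylaspartylglutamate
Nicotinate and nicotinamide metabolism	quinolinate	nicotinate
Nicotinate and nicotinamide metabolism	nicotinate	NAD
Nicotinate and nicotinamide metabolism	NAD	NADH
Nicotinate and nicotinamide metabolism	NAD	nicotinamide
Pyruvate metabolism	pyruvate	lactate
Pyruvate metabolism	pyruvate	malate
Pyruvate metabolism	pyruvate	acetate
Pyruvate metabolism	malate	oxaloacetate
Pyruvate metabolism	2-hydroxyglutarate	pyruvate
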