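reaction_id	substrates	products	oxidized	reduced
SORD	sorbitol;NAD+	fructose;NADH;H+	fructose	sorbitol
DPYD	uracil;NADH;H+	5,6-dihydrouracil;NAD+	uracil	5,6-dihydrouracil
XDH_HX	hypoxanthine;NAD+;H2O	xanthine;NADH;H+	xanthine	hypoxanthine
XDH_X	xanthine;NAD+;H2O	urate;NADH;H+	urate	xanthine
DHAR	dehydroascorbate;NADH;H+	ascorbate;NAD+	dehydroascorbate	ascorbate
LDH	pyruvate;NADH;H+	lactate;NAD+	pyruvate	lactate
MDH	malate;NAD+	oxaloacetate;NADH;H+	oxaloacetate	malate
GAPDH_POLYOL	dihydroxyacetone phosphate;NADH;H+	glycerol-3-phosphate;NAD+	dihydroxyacetone phosphate	glycerol-3-phosphate
GDH	glutamate;NAD+;H2O	alpha-ketoglutarate;NADH;H+	alpha-ketoglutarate	glutamate
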