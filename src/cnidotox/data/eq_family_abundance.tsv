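# Published top-10 toxin-family abundances for Entacmaea quadricolor:
# summed per-family mean normalised abundance (RNA across 24 tentacle
# samples; protein across 7 milked-venom samples).  Only the printed top-10
# of each dataset is available, so cross-dataset ranks outside these lists
# resolve to "Not present".
dataset	family	category	abundance
rna	Z3	Unknown	56348
rna	Sea Anemone 8	Unknown	54210
rna	ShK-like	Neurotoxins	48215
rna	IG-like	Unknown	34585
rna	Uncharacterised toxins	Unknown	24521
rna	EGF-like	Unknown	19030
rna	PLA2	Mixed function enzymes	11305
rna	Peptidase M12A	Auxiliary	8987
rna	Coagulation factor V-like	Haemostatic and haemorrhagic	8767
rna	CREC	Unknown	6308
protein	Z3	Unknown	16933968
protein	Peptidase S1	Haemostatic and haemorrhagic	9294230
protein	Venom Kunitz-type family	Protease inhibitors	6409895
protein	PLA2	Mixed function enzymes	4873099
protein	EGF-like	Unknown	4773700
protein	U15	Unknown	4298257
protein	IG-like	Unknown	3884603
protein	U12	Unknown	1416547
protein	CAP	Allergen and innate immunity	1367399
protein	NEP3	Neurotoxins	911820
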