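# Toxin family rules, evaluated in priority order (lower first).
# Columns: family, category, priority, required (model:min_count;...),
# forbidden (model;... ; the token @cross forbids any model that defines a
# different venom category), positional (A<B order, A+B adjacency, - none).
# Ordering: enzyme/structured families first, single-short-domain peptide
# families next, cysteine-scaffold families after, IG-like last before the
# engine's Uncharacterised-toxins fallback — so a multi-domain protein that
# merely contains one short neurotoxin domain is not claimed by it.
family	category	priority	required	forbidden	positional
Peptidase S1	Haemostatic and haemorrhagic	10	Trypsin:1	@cross	-
Peptidase M12A	Auxiliary	11	Astacin:1	@cross	-
Peptidase M12B	Haemostatic and haemorrhagic	12	Reprolysin:1	@cross	-
PLA2	Mixed function enzymes	13	PLA2:1	@cross	-
Venom Kunitz-type family	Protease inhibitors	14	Kunitz:1	@cross	-
Actinoporins	Pore forming	15	Actinoporin:1	@cross	-
Coagulation factor V-like	Haemostatic and haemorrhagic	16	FA5B:1	@cross	-
Ficolin lectin family	Haemostatic and haemorrhagic	17	Fibrinogen_C:1	@cross	-
C-type lectin family	Haemostatic and haemorrhagic	18	C_type_lectin:1	@cross	-
Thyroglobulin-type inhibitor	Protease inhibitors	19	TY_inhibitor:1	@cross	-
CAP	Allergen and innate immunity	20	CAP:1	@cross	-
Galectin	Allergen and innate immunity	21	Galectin:1	@cross	-
Lipocalin	Allergen and innate immunity	22	Lipocalin:1	@cross	-
Aerolysin-like	Pore forming	23	Aerolysin:1	@cross	-
MACPF-like	Pore forming	24	MACPF:1	@cross	-
DELTA-alicitoxin-Pse2b-like	Pore forming	25	AlicitoxinPse2b:1	@cross	-
DELTA-actitoxin-Ucs1a-like	Pore forming	26	ActitoxinUcs1a:1	@cross	-
ShK-like	Neurotoxins	100	ShK:1	@cross	-
NEP3	Neurotoxins	101	NEP3_dom:1	@cross	-
NEP6	Neurotoxins	102	NEP6_dom:1	@cross	-
NaTx	Neurotoxins	103	NaTx_dom:1	@cross	-
KTx2	Neurotoxins	104	KTx2_dom:1	@cross	-
KTx3	Neurotoxins	105	KTx3_dom:1	@cross	-
KTx5	Neurotoxins	106	KTx5_dom:1	@cross	-
U-actitoxin-like	Neurotoxins	107	UactX:1	@cross	-
Gigantoxin-related	Neurotoxins	108	GigTx:1	@cross	-
EGF-like	Unknown	110	EGF-like:1	@cross	-
Sea Anemone 8	Unknown	111	SeaAnem8:1	@cross	-
CREC	Unknown	112	CREC_dom:1	@cross	-
Z1	Unknown	200	Z1:1	@cross	-
Z2	Unknown	201	Z2:1	@cross	-
Z3	Unknown	202	Z3:1	@cross	-
U2	Unknown	203	U2:1	@cross	-
U8	Unknown	204	U8:1	@cross	-
U9	Unknown	205	U9:1	@cross	-
U11	Unknown	206	U11:1	@cross	-
U12	Unknown	207	U12:1	@cross	-
U13	Unknown	208	U13:1	@cross	-
U15	Unknown	209	U15:1	@cross	-
U16	Unknown	210	U16:1	@cross	-
IG-like	Unknown	300	IG-like:1	@cross	-
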