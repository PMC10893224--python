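# Domain model definitions consumed by the rule engine.
# Columns: name, type (prosite|scaffold|hmm), spec, family link.
# These descriptors are representative, user-replaceable stand-ins for the
# unpublished profile HMMs of the original annotation system: enzyme motifs
# follow the classic catalytic-site patterns, disulfide-rich peptide families
# are encoded as cysteine scaffolds (ncys=<n>;gaps=<min-max,...>).
name	type	spec	family
CAP	prosite	H-N-x(2)-R-x(2)-[VILM]-G-C	CAP
Galectin	prosite	W-G-x-E-x-R-E	Galectin
Lipocalin	prosite	G-x-W-Y-x-[LIVM]-A-K	Lipocalin
Astacin	prosite	H-E-x(2)-H-x(2)-G-F-x-H-E	Peptidase M12A
FA5B	prosite	C-x(2)-W-x(2)-G-x(4)-E-W-[LIVM]-Q	Coagulation factor V-like
Trypsin	prosite	G-D-S-G-G-P-[LIVMAKR]	Peptidase S1
Fibrinogen_C	prosite	W-W-x(2)-C-x(2)-G-x(2)-N-G	Ficolin lectin family
Reprolysin	prosite	H-E-x-G-H-x-[LIVMF]-G-x(2)-H-D	Peptidase M12B
C_type_lectin	prosite	W-I-G-L-x(2)-D-x(2)-E	C-type lectin family
PLA2	prosite	C-C-x(2)-H-D-x-C-Y	PLA2
ShK	prosite	C-x(3)-C-x(5,7)-C-x(4)-C-x-C-x(2)-C	ShK-like
NEP3_dom	prosite	C-x(2)-D-W-x(3)-C-x(4)-K-C	NEP3
NEP6_dom	prosite	C-G-x(2)-E-W-x(2)-C-x(3)-C-K	NEP6
NaTx_dom	prosite	C-L-C-x(3)-P-x(3)-G-x(3)-C	NaTx
KTx2_dom	prosite	C-S-x-D-x(2)-C-x(3)-W-C	KTx2
KTx3_dom	prosite	C-F-W-x(2)-C-x(3)-G-C	KTx3
KTx5_dom	prosite	A-C-K-D-x(2)-C-x(2)-W-C	KTx5
UactX	prosite	C-W-x(2)-N-x(2)-C-x(2)-H-C	U-actitoxin-like
GigTx	prosite	E-G-C-x(2)-W-x(2)-Y-C	Gigantoxin-related
Actinoporin	prosite	R-G-D-x(2)-W-Y-x-N	Actinoporins
AlicitoxinPse2b	prosite	W-x(2)-F-P-x(3)-Y-x(2)-K-L	DELTA-alicitoxin-Pse2b-like
ActitoxinUcs1a	prosite	Y-P-x(2)-W-x(3)-F-K-x-G	DELTA-actitoxin-Ucs1a-like
Aerolysin	prosite	G-W-x(3)-S-x(2)-F-x(2)-R-D	Aerolysin-like
MACPF	prosite	Y-G-x(2)-F-x(3)-E-x(2)-R-K	MACPF-like
Kunitz	scaffold	ncys=6;gaps=8,15,7,12,3	Venom Kunitz-type family
TY_inhibitor	prosite	Q-C-x(3)-G-x(2)-C-W-C-V	Thyroglobulin-type inhibitor
IG-like	prosite	G-x-C-x(2)-W-x(4)-D-G-x-W	IG-like
EGF-like	prosite	C-x(4)-G-x(2)-C-x(3)-N-G-x-C	EGF-like
SeaAnem8	prosite	C-x(2)-P-C-x(4)-G-W-x(2)-C	Sea Anemone 8
CREC_dom	prosite	D-x-D-G-D-G-x(2)-E	CREC
Z1	scaffold	ncys=8;gaps=3,5,2,7,4,6,3	Z1
Z2	scaffold	ncys=8;gaps=2,8,3,5,6,2,9	Z2
Z3	scaffold	ncys=8;gaps=4,6,1,8,2,5,7	Z3
U2	scaffold	ncys=6;gaps=2,9,4,7,3	U2
U8	scaffold	ncys=6;gaps=5,3,8,2,6	U8
U9	scaffold	ncys=6;gaps=1,6,9,3,4	U9
U11	scaffold	ncys=6;gaps=7,2,5,9,1	U11
U12	scaffold	ncys=6;gaps=6,4,2,8,5	U12
U13	scaffold	ncys=6;gaps=3,7,6,1,9	U13
U15	scaffold	ncys=6;gaps=8,1,4,6,2	U15
U16	scaffold	ncys=6;gaps=9,5,7,2,1	U16
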