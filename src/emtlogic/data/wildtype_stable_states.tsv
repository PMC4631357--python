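node	HS	Apop1	Apop2	Apop3	Apop4	EMT1	EMT2	M1	M2
Metastasis	0	0	0	0	0	0	0	1	1
Migration	0	0	0	0	0	0	0	1	1
Invasion	0	0	0	0	0	0	0	1	1
EMT	0	0	0	0	0	1	1	1	1
Apoptosis	0	1	1	1	1	0	0	0	0
CellCycleArrest	0	1	1	1	1	1	1	1	1
ECMicroenv	0	0	0	1	1	0	0	1	1
DNAdamage	0	1	1	1	1	1	0	1	0
GF	0	0	0	0	0	1	1	1	1
TGFbeta	0	0	0	1	1	0	0	1	1
p21	0	1	1	1	1	0	0	0	0
CDH1	1	1	1	1	1	0	0	0	0
CDH2	0	0	0	0	0	1	1	1	1
VIM	0	0	0	0	0	1	1	1	1
TWIST1	0	0	0	0	0	1	1	1	1
SNAI1	0	0	0	0	0	1	1	1	1
SNAI2	0	0	0	0	0	1	1	1	1
ZEB1	0	0	0	0	0	1	1	1	1
ZEB2	0	0	0	0	0	1	1	1	1
AKT1	0	0	0	0	0	0	0	0	0
DKK1	0	0	0	0	0	0	0	1	1
CTNNB1	0	0	0	0	0	0	0	0	0
NICD	0	0	0	0	0	0	0	1	1
p63	0	0	1	0	1	0	0	0	0
p53	0	1	0	1	0	0	0	0	0
p73	0	0	1	0	1	0	0	0	0
miR200	0	1	1	1	1	0	0	0	0
miR203	0	1	0	1	0	0	0	0	0
miR34	0	0	0	0	0	0	0	0	0
AKT2	0	0	0	0	0	1	1	1	1
ERK	0	0	0	0	0	1	1	1	1
SMAD	0	0	0	0	0	0	0	1	1
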