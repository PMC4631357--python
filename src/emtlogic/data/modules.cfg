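# Pathway modules of the metastasis model (members are model node names)
# and the mapping from model species to gene symbols used when matching
# expression data.  Flat key-value format: "<kind> <name> = v1, v2, ...".

module TGFb_pthw = TGFbeta, SMAD
module Notch_pthw = NICD
module WNT_pthw = DKK1, CTNNB1
module p53 = p53
module p63_73 = p63, p73
module miRNA = miR34, miR200, miR203
module EMT_reg = TWIST1, ZEB1, ZEB2, SNAI1, SNAI2, CDH2, VIM
module Ecadh = CDH1
module GF = GF
module ERK_pthw = ERK
module AKT1 = AKT1
module AKT2 = AKT2

# phenotype read-out -> biomarker gene
biomarker Apoptosis = CASP9
biomarker Migration = CDC42
biomarker Invasion = MMP2

# model node -> HUGO symbol (nodes absent here map to their own name)
genemap GF = EGFR
genemap ERK = MAPK1
genemap SMAD = SMAD3
genemap TGFbeta = TGFB1
genemap NICD = NOTCH1
genemap p53 = TP53
genemap p63 = TP63
genemap p73 = TP73
genemap p21 = CDKN1A
genemap miR34 = MIR34A
genemap miR200 = MIR200A
genemap miR203 = MIR203
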