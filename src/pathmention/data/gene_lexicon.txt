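# Bundled gene/protein lexicon for the deterministic lexicon recognizer.
# One symbol or multi-word name per line; matching is case-sensitive and
# token-based.  This is a small curated stand-in lexicon, not an export of
# any external tagger's model.
p53
TP53
p21
p38
ras
Ras
RAS
raf
Raf
RAF
BRAF
KRAS
HRAS
NRAS
MAPK
MAPK1
MAPK3
MAPK8
MAPK14
MEK
MEK1
MEK2
MAP2K1
ERK
ERK1
ERK2
ERK5
JNK
AKT
AKT1
AKT2
mTOR
mTORC1
PI3K
PI-3K
PIK3CA
phosphatidylinositol 3-kinase
mammalian target of rapamycin
PTEN
EGFR
HER2
ERBB2
VEGF
VEGFA
TGF
TGFB1
TNF
TNFA
IL1B
IL2
IL4
IL6
IL10
IFNG
NF-kB
NF-kappaB
NFKB1
RELA
IKK
STAT1
STAT3
STAT5
JAK1
JAK2
SMAD2
SMAD3
SMAD4
Wnt
WNT1
WNT3A
beta-catenin
CTNNB1
GSK3B
GSK-3beta
APC
Notch
NOTCH1
DLL4
Hedgehog
SHH
GLI1
SMO
BMP2
BMP4
FGF2
FGFR1
IGF1
IGF-1
IGF1R
INSR
IRS1
GRB2
SOS1
SHC1
PLCG1
PKA
PKC
PRKCA
CAMK2
CREB
CREB1
BDNF
NGF
TRKB
NTRK2
CDK1
CDK2
CDK4
CDK6
CCND1
cyclin D1
RB1
E2F1
MYC
c-Myc
JUN
c-Jun
FOS
c-Fos
MDM2
ATM
ATR
CHK1
CHK2
BRCA1
BRCA2
BAX
BCL2
BCL-2
CASP3
caspase-3
CASP8
CASP9
APAF1
CYCS
cytochrome c
FAS
FASLG
TRAIL
XIAP
BID
PARP1
HIF1A
HIF-1alpha
NRF2
NFE2L2
KEAP1
SIRT1
AMPK
PRKAA1
LKB1
STK11
FOXO1
FOXO3
PGC1A
PPARG
SREBP1
LDLR
APOE
APP
PSEN1
PSEN2
BACE1
MAPT
tau
SNCA
alpha-synuclein
LRRK2
PARK2
PINK1
HTT
SOD1
TDP-43
TARDBP
CD2
CD4
CD8
CD28
TCR
BCR
LCK
ZAP70
SYK
BTK
CXCR4
CCR5
CXCL12
RHOA
RAC1
CDC42
ROCK1
PAK1
SRC
ABL1
BCR-ABL
KIT
PDGFRA
FLT3
ALK
MET
HGF
GAB1
CBL
UBC
SUMO1
ATG5
ATG7
BECN1
beclin-1
LC3
MAP1LC3B
p62
SQSTM1
CALM1
calmodulin
CAMKK2
ITPR1
RYR2
SERCA2
ATP2A2
GRIN1
GRIN2A
GLUR1
GRIA1
DRD2
HTR2A
CHRNA7
GABRA1
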