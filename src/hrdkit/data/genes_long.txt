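# Extended homologous-recombination-repair gene list (140 symbols).
# Seeded with the 20 concise-list genes plus 120 DNA-damage-response
# symbols as an editable placeholder; substitute your preferred
# curated 140-gene list by editing this file or passing a custom list.
# BRCA1 and BRCA2 are handled separately and are intentionally absent.
ATM
ATR
BAP1
BLM
BRIP1
CDK12
CHEK1
CHEK2
FANCA
FANCC
FANCD2
FANCE
FANCF
MRE11
NBN
PALB2
RAD51B
RAD51C
RAD51D
WRN
PTEN
RAD50
RAD51
RAD51AP1
RAD52
RAD54L
RAD54B
XRCC1
XRCC2
XRCC3
XRCC4
XRCC5
XRCC6
ATRX
BARD1
ABRAXAS1
ABRAXAS2
TOPBP1
TP53BP1
RIF1
SHLD1
SHLD2
SHLD3
MAD2L2
EXO1
RECQL
RECQL4
RECQL5
DNA2
GEN1
MUS81
EME1
EME2
SLX1A
SLX4
ERCC1
ERCC4
FANCB
FANCG
FANCI
FANCL
FANCM
FAAP24
FAAP100
UBE2T
POLQ
HELQ
PARPBP
PIF1
RTEL1
FBXO18
SMARCA4
SMARCAL1
ZRANB3
HLTF
SPIDR
SWSAP1
ZSWIM7
SEM1
RPA1
RPA2
RPA3
RPA4
RMI1
RMI2
TOP3A
TOP3B
BRCC3
BABAM1
BABAM2
UIMC1
PAXIP1
LIG1
LIG3
LIG4
POLD1
POLD2
POLD3
POLD4
POLE
POLE2
PRKDC
NHEJ1
DCLRE1C
MDC1
RNF8
RNF168
HERC2
USP1
WDR48
ATMIN
MCM8
MCM9
HROB
INO80
SMARCAD1
CHD1L
NSMCE2
SMC5
SMC6
ESCO2
TONSL
MMS22L
TIMELESS
TIPIN
CLSPN
RAD17
RAD9A
RAD9B
RAD1
HUS1
RAD18
RNF4
PARP1
PARP2
PARP3
MORF4L1
H2AX
KAT5
TRIP13
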