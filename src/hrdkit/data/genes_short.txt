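# Concise homologous-recombination-repair gene list (20 symbols).
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
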