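gene	chromosome	start	end
BRCA1	chr17	43044295	43170245
BRCA2	chr13	32315086	32400268
ATM	chr11	108222484	108369102
ATR	chr3	142449235	142578826
BAP1	chr3	52401004	52410008
BLM	chr15	90717327	90816166
BRIP1	chr17	61679139	61863558
CDK12	chr17	39461486	39564237
CHEK1	chr11	125624290	125673000
CHEK2	chr22	28687743	28742422
FANCA	chr16	89737549	89816657
FANCC	chr9	95099054	95317730
FANCD2	chr3	10026438	10101930
FANCE	chr6	35452337	35467280
FANCF	chr11	22622306	22625475
MRE11	chr11	94415570	94492869
NBN	chr8	89933336	90003228
PALB2	chr16	23603165	23641310
RAD51B	chr14	67819779	68730218
RAD51C	chr17	58692602	58735611
RAD51D	chr17	35092687	35120250
WRN	chr8	31033788	31176138
PTEN	chr10	87863113	87971930
RAD50	chr5	132556954	132645000
BARD1	chr2	214725646	214809711
RAD51	chr15	40695174	40732340
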