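disease,sex_class,cases,total
ATOP,F,83,9133
ATOP,NF,745,36574
ATOP,M,169,12555
ATOP,NM,641,31828
AIHA,F,38,9133
AIHA,NF,256,36574
AIHA,M,38,12555
AIHA,NM,176,31828
CMG,F,11,9133
CMG,NF,49,36574
CMG,M,6,12555
CMG,NM,38,31828
COL,F,61,9133
COL,NF,267,36574
COL,M,109,12555
COL,NM,256,31828
ADD,F,25,9133
ADD,NF,147,36574
ADD,M,20,12555
ADD,NM,113,31828
HYPO,F,62,9133
HYPO,NF,750,36574
HYPO,M,210,12555
HYPO,NM,678,31828
IMPA,F,24,9133
IMPA,NF,170,36574
IMPA,M,56,12555
IMPA,NM,141,31828
ITP,F,21,9133
ITP,NF,262,36574
ITP,M,29,12555
ITP,NM,151,31828
IBD,F,20,9133
IBD,NF,189,36574
IBD,M,46,12555
IBD,NM,167,31828
LUP,F,6,9133
LUP,NF,74,36574
LUP,M,30,12555
LUP,NM,47,31828
PEMC,F,13,9133
PEMC,NF,71,36574
PEMC,M,11,12555
PEMC,NM,55,31828
PYO,F,176,9133
PYO,NF,27,36574
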