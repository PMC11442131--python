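# Little finger total grasp occurrence (reference)
scope,grasp,count,printed_percent
TOTAL,Adducted thumb,28,14.1
TOTAL,Lateral,32,16.1
TOTAL,Medium wrap,27,13.6
TOTAL,Parallel extension,22,11.1
TOTAL,Power sphere,73,36.7
TOTAL,Precision disc,15,7.5
TOTAL,Prismatic 4 fingers,2,1.0
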