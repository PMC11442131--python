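# Ring finger total grasp occurrence (reference)
scope,grasp,count,printed_percent
TOTAL,Adducted thumb,18,11.2
TOTAL,Lateral,62,38.5
TOTAL,Medium wrap,5,3.1
TOTAL,Power sphere,1,0.6
TOTAL,Precision disc,1,0.6
TOTAL,Precision sphere,5,3.1
TOTAL,Prismatic 4 fingers,69,42.9
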