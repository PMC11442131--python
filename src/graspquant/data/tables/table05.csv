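# Middle finger total grasp occurrence (reference); 'Precision sphere' appears twice as printed
scope,grasp,count,printed_percent
TOTAL,Precision sphere,1,0.3
TOTAL,Adducted thumb,34,9.2
TOTAL,Finger extension,32,8.6
TOTAL,Lateral,15,4.1
TOTAL,Light tool,109,29.5
TOTAL,Medium wrap,13,3.5
TOTAL,Parallel extension,10,2.7
TOTAL,Precision disc,2,0.5
TOTAL,Precision sphere,20,5.4
TOTAL,Prismatic 4 fingers,36,9.7
TOTAL,Tripod,20,5.4
TOTAL,Writing tripod,78,21.1
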