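# Index finger total grasp occurrence (reference)
scope,grasp,count,printed_percent
TOTAL,Adducted thumb,69,2.3
TOTAL,Finger extension,38,1.3
TOTAL,Lateral,42,1.4
TOTAL,Medium wrap,76,2.5
TOTAL,Palmar pinch,54,1.8
TOTAL,Power sphere,4,0.1
TOTAL,Precision disc,614,20.6
TOTAL,Precision sphere,1422,47.7
TOTAL,Prismatic 4 fingers,6,0.2
TOTAL,Tripod,545,18.3
TOTAL,Writing tripod,112,3.8
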