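# Ring finger grasp occurrence per ADL (reference)
scope,grasp,count,printed_percent
Cleaning with a cloth,Power sphere,1,100.0
Using a mouse,Precision sphere,1,100.0
Screwing a nut on a bolt,Adducted thumb,2,7.7
Screwing a nut on a bolt,Lateral,9,34.6
Screwing a nut on a bolt,Medium wrap,2,7.7
Screwing a nut on a bolt,Prismatic 4 fingers,13,50.0
Pouring juice,Precision sphere,1,100.0
Pouring milk,Precision sphere,1,100.0
Shaving,Adducted thumb,16,55.2
Shaving,Lateral,11,37.9
Shaving,Medium wrap,2,6.9
Brushing teeth,Lateral,42,42.9
Brushing teeth,Prismatic 4 fingers,56,57.1
Browsing on a phone,Precision sphere,1,100.0
Typing on a keyboard,Precision disc,1,100.0
Pouring water into a jug,Precision sphere,1,100.0
Playing with a console,Medium wrap,1,100.0
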