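# Middle finger grasp occurrence per ADL (reference); one row has no printed percent
scope,grasp,count,printed_percent
Cleaning with a cloth,Parallel extension,4,
Combing hair,Adducted thumb,5,2.6
Combing hair,Finger extension,5,2.6
Combing hair,Lateral,7,3.7
Combing hair,Light tool,109,57.4
Combing hair,Medium wrap,4,2.1
Combing hair,Parallel extension,1,0.5
Combing hair,Prismatic 4 fingers,2,1.1
Combing hair,Tripod,1,0.5
Combing hair,Writing tripod,56,29.5
Using a mouse,Precision sphere,1,100.0
Screwing a nut on a bolt,Adducted thumb,7,15.9
Screwing a nut on a bolt,Medium wrap,8,18.2
Screwing a nut on a bolt,Precision sphere,12,27.3
Screwing a nut on a bolt,Tripod,6,13.6
Screwing a nut on a bolt,Writing tripod,11,25.0
Pouring juice,Tripod,1,100.0
Pouring milk,Precision disc,1,100.0
Shaving,Medium wrap,1,100.0
Brushing teeth,Adducted thumb,22,18.5
Brushing teeth,Finger extension,27,22.7
Brushing teeth,Lateral,8,6.7
Brushing teeth,Precision sphere,7,5.9
Brushing teeth,Prismatic 4 fingers,33,27.7
Brushing teeth,Tripod,12,10.1
Brushing teeth,Writing tripod,10,8.4
Browsing on a phone,Precision disc,1,100.0
Cracking an egg,Prismatic 4 fingers,1,100.0
Typing on a keyboard,Parallel extension,5,100.0
Pouring water into a jug,Precision sphere,1,100.0
Playing with a console,Writing tripod,1,100.0
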