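# Little finger grasp occurrence per ADL (reference)
scope,grasp,count,printed_percent
Using a mouse,Parallel extension,11,91.7
Using a mouse,Precision disc,1,8.3
Screwing a nut on a bolt,Adducted thumb,4,28.6
Screwing a nut on a bolt,Lateral,1,7.1
Screwing a nut on a bolt,Power sphere,9,64.3
Pouring juice,Parallel extension,1,100.0
Pouring milk,Parallel extension,10,100.0
Shaving,Adducted thumb,15,17.6
Shaving,Medium wrap,10,11.8
Shaving,Power sphere,58,68.2
Shaving,Prismatic 4 fingers,2,2.4
Brushing teeth,Adducted thumb,9,11.8
Brushing teeth,Lateral,31,40.8
Brushing teeth,Medium wrap,16,21.1
Brushing teeth,Power sphere,6,7.9
Brushing teeth,Precision disc,14,18.4
Browsing on a phone,Medium wrap,1,100.0
Typing on a keyboard,Precision disc,1,100.0
Pouring water into a jug,Adducted thumb,4,5.8
Pouring water into a jug,Medium wrap,19,27.5
Pouring water into a jug,Parallel extension,14,20.3
Pouring water into a jug,Precision disc,13,18.8
Pouring water into a jug,Precision sphere,9,13.0
Pouring water into a jug,Prismatic 4 fingers,10,14.5
Playing with a console,Adducted thumb,1,100.0
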