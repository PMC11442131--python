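# Index finger grasp occurrence per ADL (reference)
scope,grasp,count,printed_percent
Spreading butter,Finger extension,1,12.5
Spreading butter,Precision disc,7,87.5
Cleaning with a cloth,Finger extension,16,69.6
Cleaning with a cloth,Precision disc,7,30.4
Combing hair,Precision sphere,17,65.4
Combing hair,Tripod,9,34.6
Using a mouse,Adducted thumb,5,0.4
Using a mouse,Finger extension,2,0.2
Using a mouse,Medium wrap,16,1.4
Using a mouse,Precision disc,278,24.5
Using a mouse,Precision sphere,655,57.7
Using a mouse,Tripod,180,15.8
Screwing a nut on a bolt,Lateral,21,23.1
Screwing a nut on a bolt,Palmar pinch,9,9.9
Screwing a nut on a bolt,Tripod,18,19.8
Screwing a nut on a bolt,Writing tripod,43,47.3
Picking up coins,Adducted thumb,5,19.2
Picking up coins,Precision disc,1,3.8
Picking up coins,Prismatic 4 fingers,1,3.8
Picking up coins,Tripod,13,50.0
Picking up coins,Writing tripod,6,23.1
Pouring juice,Medium wrap,1,6.3
Pouring juice,Precision sphere,12,75.0
Pouring juice,Tripod,3,18.8
Pouring milk,Precision disc,8,27.6
Pouring milk,Tripod,21,72.4
Shaving,Adducted thumb,18,58.1
Shaving,Tripod,13,41.9
Slicing,Adducted thumb,2,8.7
Slicing,Precision disc,6,26.1
Slicing,Precision sphere,13,56.5
Slicing,Tripod,2,8.7
Brushing teeth,Adducted thumb,39,2.5
Brushing teeth,Finger extension,19,1.2
Brushing teeth,Lateral,21,1.3
Brushing teeth,Medium wrap,59,3.8
Brushing teeth,Palmar pinch,44,2.8
Brushing teeth,Power sphere,4,0.3
Brushing teeth,Precision disc,307,19.6
Brushing teeth,Precision sphere,722,46.1
Brushing teeth,Prismatic 4 fingers,5,0.3
Brushing teeth,Tripod,284,18.1
Brushing teeth,Writing tripod,63,4.0
Browsing on a phone,Precision sphere,1,100.0
Cracking an egg,Precision sphere,1,100.0
Grating a lemon,Palmar pinch,1,100.0
Typing on a keyboard,Tripod,1,100.0
Pouring water into a jug,Precision sphere,1,100.0
Playing with a console,Tripod,1,100.0
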