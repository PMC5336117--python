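foot_ratio,guide_deg,vastus_lateralis,vastus_medialis,rectus_femoris
0,0,23.1,16.9,28.1
0.14,0,17.1,15.6,11.3
0.28,0,21.7,13.6,10.7
0,10,23.1,14.6,10.2
0.14,10,23.9,15.1,11
0.28,10,23.8,14.9,11.7
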