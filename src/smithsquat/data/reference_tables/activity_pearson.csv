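foot_ratio,guide_deg,vastus_lateralis,vastus_medialis,rectus_femoris
0,0,0.759,0.901,0.788
0.14,0,0.878,0.908,0.950
0.28,0,0.638,0.628,0.831
0,10,0.915,0.950,0.966
0.14,10,0.893,0.933,0.970
0.28,10,0.838,0.838,0.878
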