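foot_ratio,guide_deg,vastus_lateralis_emg,vastus_lateralis_model,vastus_medialis_emg,vastus_medialis_model,rectus_femoris_emg,rectus_femoris_model
0,0,0.62,0.55,0.60,0.53,0.62,0.53
0.14,0,0.69,0.55,0.56,0.55,0.59,0.54
0.28,0,0.67,0.50,0.65,0.50,0.62,0.50
0,10,0.57,0.54,0.53,0.54,0.57,0.53
0.14,10,0.59,0.55,0.59,0.55,0.53,0.54
0.28,10,0.61,0.55,0.61,0.55,0.61,0.55
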