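foot_ratio,guide_deg,vastus_lateralis_emg,vastus_lateralis_model,vastus_medialis_emg,vastus_medialis_model,rectus_femoris_emg,rectus_femoris_model
0,0,44.5,45.5,42.6,45.0,40.9,28.6
0.14,0,54.5,52.3,52.2,51.7,47.4,47.5
0.28,0,33.4,50.9,38.1,50.3,34.8,50.0
0,10,35.2,47.2,36.1,46.5,36.4,39.9
0.14,10,44.9,51.1,44.2,50.6,41.0,46.4
0.28,10,42.9,55.5,37.4,50.6,33.7,56.3
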