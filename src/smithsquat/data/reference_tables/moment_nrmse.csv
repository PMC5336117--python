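foot_ratio,guide_deg,hip_L,hip_R,knee_L,knee_R
0.07,5,17.8,19.9,11.8,13.4
0.07,15,18.5,23.0,14.1,18.5
0.21,5,26.0,30.4,21.1,18.6
0.21,15,31.1,47.5,15.6,19.3
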