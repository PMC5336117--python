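foot_ratio,guide_deg,hip_L,knee_L,pelvis_thorax,hip_R,knee_R
0.07,5,5.6,4.5,21.1,5.4,3.8
0.07,15,8.4,7.6,26.8,7.5,7.4
0.21,5,13.9,13.0,45.8,7.8,7.1
0.21,15,17.5,17.0,44.8,7.4,7.4
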