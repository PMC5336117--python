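foot_ratio,guide_deg,hip_L,hip_R,knee_L,knee_R
0.07,5,0.973,0.985,0.993,0.997
0.07,15,0.980,0.978,0.988,0.989
0.21,5,0.978,0.988,0.974,0.983
0.21,15,0.984,0.980,0.986,0.988
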