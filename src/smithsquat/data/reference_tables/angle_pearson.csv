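foot_ratio,guide_deg,hip_L,knee_L,pelvis_thorax,hip_R,knee_R
0.07,5,0.999,0.999,0.983,0.999,0.999
0.07,15,0.994,0.993,0.975,0.997,0.997
0.21,5,0.984,0.984,0.974,0.984,0.984
0.21,15,0.994,0.993,0.978,0.996,0.995
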