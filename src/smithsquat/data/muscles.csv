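name,side,pcsa_cm2,moment_arm_hip_m,moment_arm_knee_m
gluteus_maximus,L,45.0,-0.062,0.0
gluteus_maximus,R,45.0,-0.062,0.0
biceps_femoris,L,27.0,-0.054,0.025
biceps_femoris,R,27.0,-0.054,0.025
semitendinosus,L,14.0,-0.051,0.042
semitendinosus,R,14.0,-0.051,0.042
rectus_femoris,L,33.0,0.039,-0.044
rectus_femoris,R,33.0,0.039,-0.044
vastus_lateralis,L,59.0,0.0,-0.045
vastus_lateralis,R,59.0,0.0,-0.045
vastus_medialis,L,44.0,0.0,-0.042
vastus_medialis,R,44.0,0.0,-0.042
vastus_intermedius,L,43.0,0.0,-0.043
vastus_intermedius,R,43.0,0.0,-0.043
adductor_longus,L,16.0,0.022,0.0
adductor_longus,R,16.0,0.022,0.0
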