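# Winter-style proportional anthropometry.
#
# length_fractions: segment length as a fraction of stature h.  Sided segments
# (thigh, shank, ...) use one entry per base name.  "pelvis" is the hip-centre
# to pelvis-thorax-joint distance, "thorax" the pelvis-thorax-joint to
# shoulder distance (together 0.288 h = shoulder 0.818 h minus hip 0.530 h).
#
# mass_fractions: segment mass as a fraction of body mass; sided entries apply
# per side.  The set sums to exactly 1 (thorax carries the remainder).
length_fractions:
  pelvis: 0.100
  thorax: 0.188
  head: 0.130
  clavicle: 0.129
  scapula: 0.100
  humerus: 0.186
  ulna: 0.146
  radius: 0.146
  hand: 0.108
  thigh: 0.245
  patella: 0.030
  shank: 0.246
  talus: 0.050
  foot: 0.152
  ankle_height: 0.039
  hip_half_width: 0.0955
mass_fractions:
  pelvis: 0.142
  thorax: 0.329
  head: 0.081
  clavicle: 0.006
  scapula: 0.007
  humerus: 0.028
  ulna: 0.009
  radius: 0.007
  hand: 0.006
  thigh: 0.096
  patella: 0.004
  shank: 0.0465
  talus: 0.0045
  foot: 0.010
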