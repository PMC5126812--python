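# EQ-5D-5L value set for England (Devlin, Shah, Feng, Mulhern & van Hout,
# Health Economics 2018): additive utility decrements by dimension and level.
# Worst state 55555 scores 1 - 1.285 = -0.285.
dimension,level,decrement
MO,1,0.000
MO,2,0.058
MO,3,0.076
MO,4,0.207
MO,5,0.274
SC,1,0.000
SC,2,0.050
SC,3,0.080
SC,4,0.164
SC,5,0.203
UA,1,0.000
UA,2,0.050
UA,3,0.063
UA,4,0.162
UA,5,0.184
PD,1,0.000
PD,2,0.063
PD,3,0.084
PD,4,0.276
PD,5,0.335
AD,1,0.000
AD,2,0.078
AD,3,0.104
AD,4,0.285
AD,5,0.289
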