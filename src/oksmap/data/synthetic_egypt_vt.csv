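domain,level,decrement
constant,0,1.0
MO,2,0.08
MO,3,0.16
MO,4,0.26
MO,5,0.40
SC,2,0.07
SC,3,0.14
SC,4,0.24
SC,5,0.38
UA,2,0.06
UA,3,0.13
UA,4,0.22
UA,5,0.36
PD,2,0.09
PD,3,0.18
PD,4,0.30
PD,5,0.42
AD,2,0.07
AD,3,0.15
AD,4,0.25
AD,5,0.404
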