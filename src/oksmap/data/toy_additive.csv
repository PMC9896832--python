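domain,level,decrement
constant,0,1.0
MO,2,0.05
MO,3,0.10
MO,4,0.20
MO,5,0.30
SC,2,0.04
SC,3,0.08
SC,4,0.16
SC,5,0.26
UA,2,0.05
UA,3,0.09
UA,4,0.18
UA,5,0.28
PD,2,0.06
PD,3,0.12
PD,4,0.22
PD,5,0.33
AD,2,0.05
AD,3,0.11
AD,4,0.20
AD,5,0.30
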