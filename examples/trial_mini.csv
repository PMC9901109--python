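subject_id,arm,time,event_type
p01,treatment,5,CHF
p02,treatment,30,NONE
p03,control,3,SHK
p03,control,8,DTH
p04,control,30,NONE
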