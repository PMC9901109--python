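event_type,weight,terminal
REMI,0.2,False
CHF,0.3,False
SHK,0.5,False
DTH,1.0,True
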