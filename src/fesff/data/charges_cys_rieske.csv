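label,cys69_oxidized,cys69_reduced,cys90_oxidized,cys90_reduced,amber94
CB,0.130,0.201,0.153,0.344,-0.241
HB2,-0.001,-0.027,-0.020,-0.088,0.112
HB3,0.012,-0.013,-0.011,-0.079,0.112
SG,-0.569,-0.677,-0.632,-0.820,-0.884
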