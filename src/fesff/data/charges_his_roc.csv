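label,his183_oxidized,his183_reduced,his187_oxidized,his187_reduced,amber94
CG,0.321,0.261,0.220,0.255,-0.027
ND1,-0.325,-0.270,-0.196,-0.224,-0.381
HD1,0.377,0.362,0.350,0.351,0.365
CE1,0.120,0.121,0.041,0.103,0.206
HE1,0.143,0.148,0.148,0.140,0.139
NE2,-0.396,-0.448,-0.439,-0.542,-0.573
CD2,-0.198,-0.181,-0.128,-0.113,0.129
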