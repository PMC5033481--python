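label,his71_oxidized,his71_reduced,his93_oxidized,his93_reduced,amber94
CG,0.087,0.042,0.410,0.327,0.187
ND1,-0.237,-0.099,-0.495,-0.524,-0.543
CE1,0.039,-0.029,-0.102,-0.092,0.164
HE1,0.162,0.179,0.196,0.168,0.144
NE2,-0.231,-0.281,0.182,0.175,-0.280
HE2,0.364,0.373,0.170,0.144,0.334
CD2,-0.126,-0.129,-0.408,-0.402,-0.221
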