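system,label,observed,calculated_scaled,published_scale
fes_4cys_oxidized,B2u_b,409,427.6,1.06
fes_4cys_oxidized,Ag_b,385,390.3,1.06
fes_4cys_oxidized,B3u_b,345,342.5,1.06
fes_4cys_oxidized,B1u_t,329,329.2,1.06
fes_4cys_oxidized,Ag_t,322,304.6,1.06
fes_4cys_oxidized,B1g_b,313,298.8,1.06
fes_4cys_oxidized,B3u_t,279,261.0,1.06
fes_4cys_oxidized,Ag_FeFe,210,208.7,1.06
fes_4cys_reduced,B1_b,398,406.3,1.1
fes_4cys_reduced,A1_b,377,383.2,1.1
fes_4cys_reduced,A1_b2,307,311.1,1.1
fes_4cys_reduced,A1_t,307,262.0,1.1
fes_4cys_reduced,B1_b3,276,284.9,1.1
fes_4cys_reduced,A1_t2,258,237.1,1.1
rieske_oxidized,B1_Bu_b,433,432.7,1.03
rieske_oxidized,A1_Ag_b,410,407.6,1.03
rieske_oxidized,His_ip1,362,373.7,1.03
rieske_oxidized,His_ip2,362,373.6,1.03
rieske_oxidized,A1_Au_t,350,357.3,1.03
rieske_oxidized,B1_Bu_b2,332,344.6,1.03
rieske_oxidized,B1_Bg_b,321,325.1,1.03
rieske_oxidized,B1_Bu_b3,265,290.0,1.03
rieske_reduced,B1_b,408,415.6,1.01
rieske_reduced,A1_b,377,387.2,1.01
rieske_reduced,A1_t,315,322.1,1.01
rieske_reduced,B1_b2,307,309.2,1.01
rieske_reduced,B1_b3,297,292.2,1.01
rieske_reduced,B1_b4,246,278.9,1.01
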