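source,label,mdyne_per_A,kcal_per_mol_A2
fes_ox_exp_a,K(Fe-S(b)),1.37,197
fes_ox_exp_a,K(Fe-S(t)),1.14,164
fes_ox_exp_a,K(S-C),2.50,360
fes_ox_exp_a,K(C-C),4.80,691
fes_ox_exp_a,H(Fe-S(b)-Fe),0.45,65
fes_ox_exp_a,H(S(b)-Fe-S(b)),0.40,58
fes_ox_exp_a,H(S(b)-Fe-S(t)),0.38,55
fes_ox_exp_a,H(S(t)-Fe-S(t)),0.35,50
fes_ox_exp_a,H(Fe-S-C),0.35,50
fes_ox_exp_a,H(S-C-C),0.82,118
fes_ox_exp_a,K(Fe-Fe),0.19,27
fes_ox_exp_b,K(Fe-S(b)),1.44,207
fes_ox_exp_b,K(Fe-S(t)),1.13,163
fes_ox_exp_b,K(S-C),2.00,288
fes_ox_exp_b,K(C-C),2.50,360
fes_ox_exp_b,H(Fe-S(b)-Fe),0.27,39
fes_ox_exp_b,H(S(b)-Fe-S(b)),0.25,36
fes_ox_exp_b,H(S(b)-Fe-S(t)),0.25,36
fes_ox_exp_b,H(S(t)-Fe-S(t)),0.20,29
fes_ox_exp_b,H(Fe-S-C),0.15,22
fes_ox_exp_b,H(S-C-C),0.15,22
fes_ox_exp_b,K(Fe-Fe),0.27,39
fes_ox_calc,K(Fe-S(b)),1.450,209
fes_ox_calc,K(Fe-S(t)),1.145,165
fes_ox_calc,H(Fe-S(b)-Fe),0.627,90.
fes_ox_calc,H(S(b)-Fe-S(b)),0.634,91.
fes_ox_calc,H(S(b)-Fe-S(t)),0.488,70.
fes_ox_calc,H(S(t)-Fe-S(t)),0.488,70.
fes_ox_calc,K(Fe-Fe),0.230,33
rieske_ox_calc,K(Fe-S(b)),1.095,158.
rieske_ox_calc,K(Fe-S(t)),1.135,163.
rieske_ox_calc,K(Fe-N(t)),0.437,63.
rieske_ox_calc,H(Fe-S(b)-Fe),0.701,101.
rieske_ox_calc,H(S(b)-Fe-S(b)),0.701,101.
rieske_ox_calc,H(S(b)-Fe-S(t)),0.965,139.
rieske_ox_calc,H(S(t)-Fe-S(t)),0.885,127.
rieske_ox_calc,H(S(b)-Fe-N(t)),0.437,63.
rieske_ox_calc,H(N(t)-Fe-N(t)),0.250,36.
rieske_ox_calc,K(Fe-Fe),0.378,54.
fes_red_calc,K(Fe-S(b)):His,1.353,195.
fes_red_calc,K(Fe-S(b)):Cys,1.353,195.
fes_red_calc,K(Fe-S(t)),0.587,84.
fes_red_calc,H(Fe-S(b)-Fe),0.303,44.
fes_red_calc,H(S(b)-Fe-S(b)),0.410,59.
fes_red_calc,H(S(b)-Fe-S(t)),0.460,66.
fes_red_calc,H(S(t)-Fe-S(t)),0.460,66.
fes_red_calc,K(Fe-Fe),0.164,24.
rieske_red_calc,K(Fe-S(b)):His,0.949,137.
rieske_red_calc,K(Fe-S(b)):Cys,0.874,126.
rieske_red_calc,K(Fe-S(t)),1.169,168.
rieske_red_calc,K(Fe-N(t)),0.411,59.
rieske_red_calc,H(Fe-S(b)-Fe),0.373,54.
rieske_red_calc,H(S(b)-Fe-S(b)),0.373,54.
rieske_red_calc,H(S(b)-Fe-S(t)),0.335,48.
rieske_red_calc,H(S(t)-Fe-S(t)),0.335,48.
rieske_red_calc,H(S(b)-Fe-N(t)),0.401,58.
rieske_red_calc,H(N(t)-Fe-N(t)),0.401,58.
rieske_red_calc,K(Fe-Fe),0.246,35.
roc_mono,mode-598,0.505,72.7
roc_mono,mode-501,0.607,87.3
roc_mono,mode-483,0.439,63.2
roc_mono,mode-302,0.262,37.7
roc_mono,mode-252,0.211,30.4
roc_mono,mode-238,0.179,25.8
roc_mono,mode-208,0.208,29.9
roc_bi,mode-592,0.547,78.7
roc_bi,mode-448,0.442,63.6
roc_bi,mode-338,0.194,27.9
roc_bi,mode-269,0.402,57.8
roc_bi,mode-262,0.309,44.5
roc_bi,mode-198,0.147,21.2
worked_example,K(Fe-Fe)-mode210,0.22,32
worked_example,K(Fe-S(t))-mode313,1.01,145
worked_example,K(Fe-S(b))-mode329,2.03,292
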