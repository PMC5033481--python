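fesff parameters | stretch/bend convention: full (K_file = k)
MASS
FE     55.8450
SB     32.0600
ST     47.0950

BOND
FE-FE   33.00   2.710

ANGL
SB-FE-ST    70.00    110.60

DIHE
FE-SB-FE-SB   1    1.0000     0.0  -1.0
FE-SB-FE-SB   1    2.5000   180.0   2.0

NONB

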