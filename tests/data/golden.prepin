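    0    0    2

CYR residue template (fesff)
cyr.res
CYR  INT  0
CORRECT     OMIT DU   BEG
  0.0000
   1  DUMM  DU    M    0   0   0     0.000       0.0         0.0       0.00000
   2  DUMM  DU    M    1   0   0     1.449       0.0         0.0       0.00000
   3  DUMM  DU    M    2   1   0     1.523     111.21        0.0       0.00000
   4  CB  CT  M    3   2   1     1.626     56.07      180.00   0.130000
   5  HB2 H1  M    4   3   2     1.082      1.02        0.00  -0.001000
   6  HB3 H1  M    5   4   3     1.825     34.84      196.72   0.012000
   7  SG  SH  M    6   5   4     2.052     54.77       90.04  -0.569000

LOOP

IMPROPER

DONE
STOP
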