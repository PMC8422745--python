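population,PJ,SL,AS,DL,SY,SH,JN
PJ,0,0.0021,0.0011,0.0009,0.0012,0.0014,0.0026
SL,0.0021,0,0.0019,0.0017,0.0019,0.0021,0.0034
AS,0.0011,0.0019,0,0.0007,0.0010,0.0012,0.0024
DL,0.0009,0.0017,0.0007,0,0.0008,0.0010,0.0021
SY,0.0012,0.0019,0.0010,0.0008,0,0.0013,0.0026
SH,0.0014,0.0021,0.0012,0.0010,0.0013,0,0.0027
JN,0.0026,0.0034,0.0024,0.0021,0.0026,0.0027,0
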