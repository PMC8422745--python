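population,tau,theta0,theta1,SSD,HRI
DL,3.000,0.000,0.341,0.003,0.322
PJ,3.000,0.000,0.571,0.010,0.240
AS,3.000,0.000,0.421,0.018,0.359
SL,1.387,0.000,99999.000,0.007,0.070
SY,0.768,0.000,99999.000,0.003,0.098
SH,0.861,0.000,99999.000,0.013,0.130
JN,0.469,0.000,9.455,0.007,0.190
pooled,1.783,0.000,42858.255,0.009,0.201
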