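population,location,latitude,longitude,n
DL,Liaoning Dalian Sha River,39.622,122.067,46
PJ,Liaoning Panjin Shuangtaizi River,41.180,122.067,44
AS,Liaoning Anshan Yangliu River,41.082,122.847,47
SL,Liaoning Shenyang Longwei Lake,41.842,123.589,47
SY,Liaoning Shenyang Yangshi reservoir,41.978,123.691,48
SH,Liaoning Shenyang Huangjia Liao River,42.146,123.472,48
JN,Shandong Jining Dushan Lake,35.033,116.702,46
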