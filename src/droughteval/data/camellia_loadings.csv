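indicator,PC1,PC2,PC3
Lth,0.264,0.054,0.372
UET,0.222,0.301,0.069
LET,0.188,0.374,0.015
PT,0.249,-0.003,0.537
ST,0.249,0.022,0.251
SD,0.088,0.482,-0.171
SA,0.255,-0.197,0.078
SL,0.224,-0.274,-0.160
SW,0.261,-0.159,0.087
SOC,0.251,0.023,0.168
MDA,-0.264,0.130,0.233
CRC,0.101,0.488,-0.138
CAT,-0.239,0.259,0.153
POD,-0.251,0.141,0.323
SOD,-0.263,0.063,0.006
Pro,-0.271,0.053,0.066
SS,-0.250,-0.208,0.096
SP,-0.250,-0.043,0.441
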