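Gene0001
Gene0009
Gene0011
Gene0020
Gene0023
Gene0024
Gene0026
Gene0029
Gene0034
Gene0051
Gene0052
Gene0065
Gene0068
Gene0078
Gene0084
Gene0085
Gene0087
Gene0089
Gene0094
Gene0099
Gene0110
Gene0113
Gene0120
Gene0121
Gene0128
Gene0130
Gene0131
Gene0132
Gene0148
Gene0156
Gene0163
Gene0171
Gene0174
Gene0187
Gene0189
Gene0210
Gene0215
Gene0220
Gene0231
Gene0232
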