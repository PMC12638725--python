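sex	points	risk
F	-2	0.009
F	-1	0.010
F	0	0.012
F	1	0.015
F	2	0.018
F	3	0.021
F	4	0.025
F	5	0.029
F	6	0.034
F	7	0.040
F	8	0.048
F	9	0.056
F	10	0.066
F	11	0.078
F	12	0.091
F	13	0.107
F	14	0.125
F	15	0.146
F	16	0.170
F	17	0.198
F	18	0.229
F	19	0.265
F	20	0.305
F	21	0.320
M	-3	0.009
M	-2	0.011
M	-1	0.014
M	0	0.016
M	1	0.019
M	2	0.023
M	3	0.028
M	4	0.033
M	5	0.039
M	6	0.047
M	7	0.056
M	8	0.067
M	9	0.079
M	10	0.094
M	11	0.112
M	12	0.132
M	13	0.156
M	14	0.184
M	15	0.216
M	16	0.253
M	17	0.294
M	18	0.320
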