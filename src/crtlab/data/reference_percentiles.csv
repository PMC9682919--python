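# Normative cumulative percentiles for the 50-item online CRT,
# transcribed from the published normative table for 282,140 valid
# first tests.  Count metrics (n_correct, hits, crs) give the fraction
# of tests STRICTLY BELOW the threshold; rt gives the fraction of
# tests STRICTLY SLOWER than the threshold (seconds).
metric,threshold,fraction
n_correct,30,0.003
n_correct,31,0.005
n_correct,32,0.010
n_correct,33,0.014
n_correct,34,0.018
n_correct,35,0.023
n_correct,36,0.029
n_correct,37,0.037
n_correct,38,0.049
n_correct,39,0.064
n_correct,40,0.086
n_correct,41,0.115
n_correct,42,0.155
n_correct,43,0.209
n_correct,44,0.280
n_correct,45,0.371
n_correct,46,0.479
n_correct,47,0.601
n_correct,48,0.729
n_correct,49,0.851
n_correct,50,0.949
hits,9,0.003
hits,10,0.004
hits,11,0.005
hits,12,0.007
hits,13,0.009
hits,14,0.012
hits,15,0.017
hits,16,0.023
hits,17,0.033
hits,18,0.048
hits,19,0.069
hits,20,0.101
hits,21,0.151
hits,22,0.228
hits,23,0.345
hits,24,0.521
hits,25,0.766
crs,9,0.003
crs,10,0.005
crs,11,0.007
crs,12,0.009
crs,13,0.011
crs,14,0.015
crs,15,0.019
crs,16,0.026
crs,17,0.035
crs,18,0.051
crs,19,0.077
crs,20,0.119
crs,21,0.186
crs,22,0.286
crs,23,0.431
crs,24,0.617
crs,25,0.828
rt,0.5,1.000
rt,0.6,0.992
rt,0.7,0.914
rt,0.8,0.716
rt,0.9,0.475
rt,1.0,0.282
rt,1.1,0.156
rt,1.2,0.083
rt,1.3,0.044
rt,1.4,0.023
rt,1.5,0.012
rt,1.6,0.006
rt,1.7,0.003
rt,1.8,0.002
rt,1.9,0.001
rt,2.0,0.000
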