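measure,group,n,mean,sd
chronological_age,TD,40,4.59,1.34
chronological_age,AS,48,4.24,1.22
chronological_age,ID,43,4.56,1.67
DP3,TD,36,4.32,1.49
DP3,AS,37,1.49,0.53
DP3,ID,36,1.94,0.80
INDT_ASD,TD,37,0.16,0.37
INDT_ASD,AS,37,17.16,4.35
INDT_ASD,ID,39,5.15,7.51
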