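cluster_id,mean_eV,sd_eV
1,-556.38,2.73
2,-557.24,2.31
3,-555.47,2.59
4,-555.58,3.13
5,-557.54,1.76
6,-558.11,1.79
7,-556.73,2.44
8,-556.78,2.66
9,-557.07,2.48
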