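locus,population,n_AA,n_AB,n_BB
C1146T,STH,6,12,7
C1146T,SFK x STH,12,14,4
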