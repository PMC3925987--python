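m,p,r_u,rr
3000,0.40,0.30,1.50
2500,0.40,0.30,1.50
2500,0.40,0.30,1.50
2000,0.40,0.30,1.50
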