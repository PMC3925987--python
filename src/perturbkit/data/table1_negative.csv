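m,p,r_u,rr
2500,0.24,0.4737,1.7593
2500,0.40,0.3333,2.4000
2500,0.60,0.2000,2.3333
2500,0.76,0.1667,1.8947
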