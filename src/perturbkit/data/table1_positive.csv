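m,p,r_u,rr
2500,0.76,0.6667,1.2632
2500,0.60,0.4000,1.1667
2500,0.40,0.3333,1.2000
2500,0.24,0.1579,1.0556
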