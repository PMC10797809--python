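F,G,H,I,J
0.7,0.1,0.1,0,0.1
0,0.5,0.2,0.1,0.2
0.6,0.1,0.15,0,0.15
0.55,0.1,0.1,0.15,0.1
0.6,0.1,0.2,0,0.1
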