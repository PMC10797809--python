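F,G,H
0.5,0.2,0.3
0.5,0.2,0.3
0,0.9,0.1
0.5,0.2,0.3
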