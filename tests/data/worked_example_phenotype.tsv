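A	10
B	10
C	2
D	10
E	2
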