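Gene1,Gene2,Sign
g1,g2,+
g2,g3,+
g3,g4,+
g4,g5,+
g5,g1,+
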