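# nodes: X1 X2 X3 X4 X5
# five-node ring with two 2-cycles not sharing a node
X1 -> X2
X2 -> X3
X3 -> X4
X4 -> X5
X5 -> X1
X2 -> X1
X4 -> X3
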