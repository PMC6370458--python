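# nodes: X1 X2 X3 X4 X5 X6 X7 X8 X9 X10
# ten-node ring with four node-disjoint 2-cycles
X1 -> X2
X2 -> X3
X3 -> X4
X4 -> X5
X5 -> X6
X6 -> X7
X7 -> X8
X8 -> X9
X9 -> X10
X10 -> X1
X2 -> X1
X4 -> X3
X6 -> X5
X8 -> X7
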