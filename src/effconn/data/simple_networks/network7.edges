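# nodes: In X1 X2 X3 X4 Out
# one node feeds into a 4-cycle which feeds into a single node
In -> X1
X1 -> X2
X2 -> X3
X3 -> X4
X4 -> X1
X3 -> Out
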