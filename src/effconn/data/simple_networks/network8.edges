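# nodes: In X1 X2 X3 X4 X5 X6 Out
# second-order cyclic system: 6-node outer cycle with an inner 4-cycle chord
In -> X1
X1 -> X2
X2 -> X3
X3 -> X4
X4 -> X5
X5 -> X6
X6 -> X1
X4 -> X1
X6 -> Out
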