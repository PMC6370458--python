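# nodes: A B X Y Z1 Z2 Z3
# two nodes feed into a 2-cycle which branches into three nodes
A -> X
B -> X
X -> Y
Y -> X
Y -> Z1
Y -> Z2
Y -> Z3
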