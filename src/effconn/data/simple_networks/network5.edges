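# nodes: A B X Y Z
# two nodes feed into a 2-cycle which feeds into a single node
A -> X
B -> Y
X -> Y
Y -> X
Y -> Z
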