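# nodes: In A1 A2 A3 A4 B1 B2 B3 Out
# one node feeds a 4-cycle sharing node A4 with a second 4-cycle feeding out
In -> A1
A1 -> A2
A2 -> A3
A3 -> A4
A4 -> A1
A4 -> B1
B1 -> B2
B2 -> B3
B3 -> A4
B3 -> Out
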