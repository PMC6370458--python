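"""Scoring an estimated directed graph against a ground truth.

Shows the three evaluation levels on a worked miniature: adjacencies are
unordered pairs (a 2-cycle is one adjacency), orientations are directed
edges (a 2-cycle is two), and 2-cycles are pairs with both directions.
"""

from effconn.graphs import DirectedGraph
from effconn.metrics import cycle_census, evaluate_graphs, matthews_correlation

nodes = ["X", "Y", "Z"]
truth = DirectedGraph(nodes, [("X", "Y"), ("Y", "Z"), ("Z", "Y")])
estimate = DirectedGraph(nodes, [("X", "Y"), ("Y", "Z"), ("X", "Z")])

report = evaluate_graphs(estimate, truth)
print(report.to_tsv())
# AP = 2/3: of the estimate's three adjacencies, X-Z is spurious.
# OR = 2/3: the estimate misses the feedback direction Z -> Y.
# 2CP is NaN (nothing to be precise about: no 2-cycle was estimated),
# 2CR = 0: the true Y <=> Z feedback went undetected.

print("orientation-level MCC:",
      round(matthews_correlation(estimate, truth, "orientation"), 3))
print("truth cycle census (n2, cycles, max, mean):", cycle_census(truth))
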