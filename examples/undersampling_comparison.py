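"""Temporal undersampling: lag-based vs i.i.d. search methods.

Simulates the 10-node network with four node-disjoint 2-cycles at two
acquisition rates (TR 1.2 s and TR 3 s, both 500 datapoints per session)
and compares conditional multivariate Granger causality against FASK.
Lag-based inference leans on temporal precedence and loses recall when the
sampling interval grows; FASK treats records as i.i.d. draws and is
unaffected.
"""

import numpy as np
import pandas as pd

from effconn import build_simple_network, simple_network_skeleton
from effconn.baselines import mvgc_search
from effconn.fask import FaskConfig, fask_search
from effconn.metrics import evaluate_graphs
from effconn.simulate import SimulationConfig, concatenate_sessions, make_session

truth = simple_network_skeleton(4)
results = {}
for tr in (1.2, 3.0):
    rng = np.random.default_rng(int(tr * 100))
    config = SimulationConfig(duration=500 * tr, tr=tr)
    pool = [make_session(config, build_simple_network(4, "amplifying", rng), rng)
            for _ in range(12)]
    rows = {}
    for rep in range(3):
        chosen = rng.choice(12, 10, replace=False)
        data = concatenate_sessions([pool[i].y_observed for i in chosen])
        for name, search in [
            ("MVGC", lambda d: mvgc_search(d, 1e-5, 5, truth.nodes)),
            ("FASK", lambda d: fask_search(d, FaskConfig(), truth.nodes)),
        ]:
            rep_metrics = evaluate_graphs(search(data), truth).as_dict()
            rows.setdefault(name, []).append(rep_metrics)
    results[tr] = {name: pd.DataFrame(r).mean() for name, r in rows.items()}

for name in ("MVGC", "FASK"):
    print(f"\n{name}: recall (adjacency / orientation / 2-cycle)")
    for tr in (1.2, 3.0):
        m = results[tr][name]
        print(f"  TR {tr} s: {m['AR']:.2f} / {m['OR']:.2f} / {m['2CR']:.2f}")
# MVGC's recalls fall at TR 3 while FASK's stay flat: information carried by
# lagged dependence decays with the sampling interval, i.i.d. skewness does not
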