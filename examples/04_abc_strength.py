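"""Rejection-ABC estimation of the filtering strength t.

Using filtering-labelled reference simulations, accepts the 100 rows whose
SD-scaled top-10 statistics sit closest to an observed community simulated at
known strength (t = 4, strong), and summarises the posterior sample of t with
its median and 90/95% highest-density intervals.  Small t = strong filtering.
"""

import numpy as np
import pandas as pd

from kipuka import abc_reject, simulate_reference_table, train_rf
from kipuka.assembly import AssemblyParams, assemble_local, simulate_birth_death_tree, simulate_traits
from kipuka.summary_stats import STAT_NAMES, compute_stats_fast

conditions = {"n_regional": 150, "n_local_values": [15]}
ref = simulate_reference_table(400, data_conditions=conditions, seed=5)
clf = train_rf(ref, n_trees=300, seed=6, n_trees_importance=100)

rng = np.random.default_rng(11)
tree = simulate_birth_death_tree(150, 0.8, 0.1, rng)
x = simulate_traits(tree, rng, model="OU", sigma2=0.92, alpha=0.2, theta=4.8)
comm = assemble_local(
    (tree, x), AssemblyParams(model="filtering", tau=4.0, n_local=15, n_regional=150), rng
)
obs = pd.Series(compute_stats_fast(tree, x, comm.member_idx, rng), index=STAT_NAMES)

filtering_rows = ref.loc[ref["model"] == "filtering"]
res = abc_reject(filtering_rows, obs, clf.result.importance, top_k=10, n_accept=100, seed=0)

print(f"true strength t = 4.0 (prior U(1, 60); small = strong filtering)")
print(f"posterior median t = {res.median_t:.1f}")
print(f"90% HDI: [{res.hdi90[0]:.1f}, {res.hdi90[1]:.1f}]")
print(f"95% HDI: [{res.hdi95[0]:.1f}, {res.hdi95[1]:.1f}]")
print("statistics used:", ", ".join(res.top_stats))
print(
    "\nThe posterior pulls well below the prior mean (30.5) toward the strong-"
    "filtering truth; with one 15-species community the intervals stay broad."
)
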