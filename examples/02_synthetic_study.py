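"""Generate the default synthetic study and inspect its statistical structure.

The generator reproduces, at desk scale, the two dataset properties the
package's analyses revolve around: a heavy-tailed PPI degree distribution and
a hub-concentrated interaction matrix (top 5% of proteins holding ~40% of the
links). The feature model plants a cosine-similarity signal whose strength is
calibrated so the Bayes-optimal scorer reaches MicroAUC_p ~ 0.9.
"""

import numpy as np

from graphdti import SimConfig, generate_dataset, micro_auc
from graphdti.simulate import _grid_prediction_set, oracle_cosines, top_share

config = SimConfig(seed=1)  # 500 proteins, 100 drugs, 4000 links, 64-dim
ds = generate_dataset(config)

degrees = np.array(list(ds.graph.degrees().values()))
print(f"PPI network  : {ds.graph.n_nodes} proteins, {ds.graph.n_edges} edges")
print(f"degree       : median {np.median(degrees):.0f}, max {degrees.max()} (heavy tail)")
print(f"hub-bias DTI : top-5% proteins hold {top_share(ds.hub_dti):.1%} of interactions")

C = oracle_cosines(ds.graph, ds.hub_dti, config)
bayes, _ = micro_auc(_grid_prediction_set(ds.dti, C), axis="protein")
print(f"Bayes scorer : MicroAUC_p {bayes:.3f} (ceiling any model can reach)")
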