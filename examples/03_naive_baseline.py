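"""The degree-based naive predictor: how far does hub bias alone carry you?

P_k ranks proteins by their number of known drug interactions in the training
folds and predicts, for every drug, the top k proteins. It uses no chemistry
and no biology — any performance above 0.5 quantifies dataset bias.
"""

import numpy as np

from graphdti import SimConfig, make_split
from graphdti.baseline import sweep_k_cv
from graphdti.simulate import generate_hub_biased_dti, generate_ppi_graph

for label, skew in [("hub-biased (calibrated default)", None), ("uniform degrees", 0.0)]:
    aucs = []
    for seed in range(5):
        cfg = SimConfig(seed=seed) if skew is None else SimConfig(hub_skew=skew, seed=seed)
        graph = generate_ppi_graph(cfg)
        dti = generate_hub_biased_dti(graph, cfg)
        plan = make_split(dti, "pair", 5, seed=seed)
        per_fold = sweep_k_cv(dti, plan)  # best (k, MacroAUC) per rotation
        aucs.append(np.mean([a for _, a in per_fold]))
    print(f"{label:35s}: best MacroAUC {np.mean(aucs):.3f} +- {np.std(aucs):.3f}")

print(
    "\nThe gap between the two rows is pure dataset bias: a predictor that"
    "\nignores the drug entirely looks far better than chance whenever hub"
    "\nproteins concentrate the known interactions."
)
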