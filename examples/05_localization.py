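"""Does the PPI graph help? Only if the features localize on it.

Trains the graph variant and the pruned variant (identical MLP/normalization
capacity, aggregation removed) on synthetic data where the interaction signal
either spreads over graph neighborhoods (localized) or sits on each protein
alone (iid). Scaled down to 2 seeds for a quick run; the full protocol uses 5.
"""

from graphdti import localization_experiment

result = localization_experiment(n_seeds=2, seed=0)
print(result.summary.to_string(index=False))
print()
print(result.deltas.to_string(index=False))
print(
    "\nReading: in localized mode the graph variant beats its graph-blind twin"
    "\n(the delta is the value of the network information itself, not of the"
    "\nextra parameters); in iid mode the delta sits at zero."
)
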