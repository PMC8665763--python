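# graphdti

Drug–target interaction (DTI) prediction over protein–protein interaction
(PPI) networks, together with the evaluation machinery needed to tell real
biological signal apart from dataset bias.

## The problem

Predicting which drugs physically interact with which proteins is a binary
classification problem over the drug × protein grid, with two awkward
properties. First, the useful signal for a protein is often not on the
protein itself: phenotypic and functional features *localize* on the
interaction network — neighboring proteins share them — so a model that can
pool information over the PPI graph should beat one that cannot. Second,
public DTI databases are heavily hub-biased (a few percent of proteins hold
a large share of all known interactions), which lets even a feature-free
predictor look good under the usual pair-split cross-validation.

`graphdti` implements both sides of this story:

* **Model.** Per-entity trainable feature transformations (affine +
  LeakyReLU), a stack (height 3) of residual graph-convolution blocks over
  the PPI network, and a *half-twin* scorer
  `y(d,p) = σ(α·cos(u_d, u_p) + β)` on the resulting embeddings. Two layer
  families are provided: **GCNConv**,
  `X' = D̂^(−1/2)(A+I)D̂^(−1/2) X Θ`, and **GENConv**,
  `x_i' = MLP(x_i + AGG({σ(x_j + e_ji) + ε}))` with sum / mean / softmax /
  power aggregation. The class imbalance is compensated by weighting positive
  pairs with `w = |D|·|P| / |Int|` in the cross-entropy, computed on the
  training fold. A **pruned** variant removes the aggregation term while
  keeping the MLP/normalization path — same parameter budget, no graph — so
  "the graph helps" can be separated from "more parameters help".
* **Evaluation.** Cross-validation split over pairs, drugs, or proteins (the
  protein split is the cold-start regime); **MacroAUC** over pooled pairs;
  **MicroAUC_p / MicroAUC_d**, the unweighted mean of per-protein
  (per-drug) AUROCs, where single-class entities are imputed with thresholded
  accuracy rather than silently dropped; one-sided Welch t-tests with
  Bonferroni correction for method comparison.
* **Naïve baseline.** `P_k` ranks proteins by their number of training
  interactions and predicts, for *every* drug, the top k proteins. It reads
  no features; its MacroAUC above 0.5 is a direct measurement of hub bias.
* **Synthetic data.** A preferential-attachment PPI graph, a hub-biased
  interaction matrix (skew calibrated so the top 5% of proteins hold ~40% of
  links), and latent-factor features that either localize on the graph or
  don't — with the interaction signal calibrated so the Bayes-optimal scorer
  reaches MicroAUC_p ≈ 0.9.

Real data is read from STRING-dialect PPI TSVs, STITCH-dialect or bare
edge-list DTI tables, and plain per-entity feature TSVs, with the standard
confidence-700 filtering.

## Worked example

```bash
python examples/03_naive_baseline.py
```

prints (5 seeds, pair-split CV on the default 500-protein / 100-drug /
4000-interaction synthetic study):

```
hub-biased (calibrated default)    : best MacroAUC 0.768 +- 0.002
uniform degrees                    : best MacroAUC 0.510 +- 0.004
```

A predictor that ignores the drug entirely reaches MacroAUC ≈ 0.77 purely by
recommending hub proteins — the gap to 0.51 on degree-uniform data is the
bias a pair-split evaluation lets a model exploit.

```bash
python examples/05_localization.py
```

prints (2 seeds; the full 5-seed protocol is in `tests/test_acceptance.py`):

```
     mode   arch     mean       sd  n
      iid  graph 0.652207 0.004361  2
      iid pruned 0.648416 0.012182  2
localized  graph 0.695644 0.002870  2
localized pruned 0.631703 0.003054  2

     mode  delta_mean  delta_sd
localized    0.063941  0.005925
      iid    0.003791  0.007821
```

The graph-minus-pruned delta is positive only when the interaction signal
actually spreads over graph neighborhoods: network information, not
parameter count, is what the graph variant buys. Other examples cover I/O
and alignment (`01`), the synthetic study's structure (`02`), and cold-start
training/evaluation (`04`). A thin CLI (`graphdti simulate|train|evaluate|
baseline|compare|localization-experiment`) wraps the same functions for
shell use.

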