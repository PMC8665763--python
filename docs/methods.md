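# Methods

## Problem and model

Given a set of drugs D with feature vectors, a set of proteins P with feature
vectors, and a PPI network G = (V, E) over P, we treat DTI prediction as
binary classification over D × P, with every unobserved pair counted as a
negative. The model has three stages:

1. **Feature transformation.** One trainable affine map + LeakyReLU per
   feature source (drug side and protein side separately), projecting
   heterogeneous inputs to a common embedding width (default 64). Multiple
   sources per side are concatenated (`concat_features`) before the
   transform. Weight matrices are initialized semi-orthogonally; when the
   two sides have equal input width they share the initial matrix, so the
   cosine scorer starts from an undistorted similarity space (the branches
   diverge freely during training).
2. **Graph propagation** (protein side only). A stack of height 3 of
   residual blocks `X ← X + MLP(norm(x_i + AGG({σ(x_j + e_ji) + ε})))`.
   The layer family is GENConv with sum / mean / softmax (learnable
   temperature) / power (learnable exponent) aggregation; softmax is the
   default. GCNConv (`X' = D̂^(−1/2)(A+I)D̂^(−1/2)XΘ`) is provided as the
   reference convolution and is cross-checked against a dense implementation.
   ε is a fixed 1e-7 per channel. Edge features are zero for binary graphs;
   enabling weighted propagation broadcasts the STRING confidence per
   channel. Receptive field radius equals stack height; isolated nodes
   aggregate the zero vector (not an error, since alignment may retain
   proteins without edges).
3. **Half-twin scorer.** `y(d,p) = σ(α·cos(u_d, u_p) + β)` with learnable
   scalars (α init 1, β init 0); the cosine of a zero vector is defined as 0.

**Block wiring.** The normalization inside each residual block standardizes
*each node's vector across channels* (learnable per-channel affine) and is
applied to the MLP input, i.e. after aggregation. Two alternatives were
rejected for cause: (a) standardizing each feature *across nodes* couples
every node to every other through the batch statistics, which destroys the
locality guarantee (a perturbation outside the height-hop neighborhood must
change nothing, exactly); (b) normalizing *before* message passing re-centers
the nonnegative-dominated LeakyReLU embeddings, so the ReLU message
activation discards half of every neighbor's signal — empirically this
wiring could not learn neighborhood averaging at all. The MLP's second layer
is zero-initialized, so every block starts as the identity and the graph
path is learned only where it reduces the loss; this is also what keeps the
graph variant from underperforming its pruned twin on non-localized data.

**Pruned ablation.** The same blocks with the aggregation term replaced by
the zero vector. The MLP/normalization path and its parameter count are
identical (the full stack carries exactly one extra scalar per
softmax/power block); the output provably ignores the edge set. This is the
control that separates "the graph adds parameters" from "the graph adds
information".

## Loss, imbalance and training protocol

Positives are a small fraction of the grid, so the binary cross-entropy
weights positive pairs by `w = |D|·|P| / |Int|` (`compute_positive_weight`).
Two weighting modes exist: `positive_term` (default) multiplies only the
positive-label term by w — weighting positive *samples*; `both_terms`
multiplies the entire per-pair loss by w, which merely rescales the loss but
is kept for completeness. w is computed from the training fold's own counts;
using the full dataset would leak the held-out fold's link counts.

Training is full-batch Adam (lr 3e-2, standard moment decays): the
propagation stack runs once per step and all training pairs are scored
against it, which on desk-scale problems is far cheaper per epoch than
per-drug batching (a `drug_batch_size` option restores smaller batches).
Optional negative subsampling applies to training pairs only; the validation
and test paths score every pair and contain no sampler. Early stopping
tracks the validation fold's MicroAUC_p (the protein-centric metric the
model is selected for) with patience 30 over at most 300 epochs, returning
the best-epoch parameters. Scores are clamped to [1e-7, 1−1e-7] inside the
loss.

**Denoising jitter.** Fresh Gaussian noise (sd 2.0 by default) is added to
the protein features at every *training* epoch. The cosine scorer is
scale-invariant, so weight decay cannot regularize this model; without any
regularizer the network memorizes training proteins through their exact
feature vectors (training MicroAUC_p → 0.99 while cold-start validation
stalls). Input jitter directly breaks that lookup and, on localized data,
additionally rewards neighborhood averaging — the behavior the graph stack
is there to learn.

With 5-fold cross-validation, fold i is the test fold and fold i+1 (cyclic)
the validation fold. With exactly 2 folds the non-test fold is split 4:1
into train and validation (the plain rotation would leave no training
units).

## Evaluation

* **MacroAUC**: trapezoidal AUROC over all pooled pairs; equal to the
  Mann–Whitney probability with half-credit for ties (asserted against an
  O(n²) oracle). Single-class input is an error here by contract.
* **MicroAUC_p / MicroAUC_d**: unweighted mean of per-entity AUROCs. An
  entity whose pairs are single-class (no positive, or no negative — treated
  symmetrically) has no AUROC; it is imputed with the accuracy of
  predictions thresholded at 0.5 (threshold exposed). The unimputed variant
  (entities omitted) is reported alongside. Per-entity AUROCs use the
  rank-sum formula with average ranks, identical to the trapezoidal value.
  In cross-validation the metric is computed per test fold over test-fold
  entities only — the only pairs with honest predictions — and fold values
  feed the significance tests.
* **Method comparison**: one-sided Welch t-test (H1: mean A > mean B) with
  Bonferroni correction `p_adj = min(1, m·p)`; a paired variant is available.
  Two zero-variance samples with equal means return p = 0.5, flagged.

## Naïve baseline

`P_k` ranks proteins descending by their training interaction count (ties
broken lexicographically; unseen proteins rank last with count 0) and scores
1 for the top k proteins, for every drug. Binary scores make the ROC three
points, so MacroAUC_k = (1 + TPR_k − FPR_k)/2; the k-sweep evaluates this
closed form for all k at once from cumulative counts (asserted equal to
running `macro_auc` on the thresholded predictions). The default sweep covers
every k in 0..|P|; a boundaries-only grid is available. Under a protein
split the baseline is undefined — held-out proteins have no training
counts — and the CV driver raises. A graded variant (score = 1 − rank/|P|)
exists for smoother curves but is not the baseline's definition.

## Synthetic data

The generator reproduces, at desk scale, the dataset structure the analyses
depend on. One global seed expands into independent substreams
(graph / interactions / features), so changing the feature mode never
changes the graph. Defaults: 500 proteins, 100 drugs, 4000 interactions,
64-dimensional features.

* **PPI graph**: Barabási–Albert preferential attachment (3 edges per new
  node) — connected, heavy-tailed, no self-loops. Real database topology is
  out of scope; only the hub structure matters for the bias analyses.
* **Hub-biased interactions**: exactly `n_links` distinct pairs drawn
  without replacement with protein marginals ∝ rank^(−hub_skew) over the
  PPI-degree ranking, drugs uniform. `hub_skew` = 1.156, set by bisection so
  the top 5% of proteins hold 40% (±0.5% at calibration) of the
  interactions — the concentration reported for large public DTI resources;
  `hub_skew = 0` gives uniform proteins.
* **Features and relabeled interactions**: drugs get i.i.d. standard-normal
  latents z_d. Protein latents start i.i.d.; in *localized* mode they are
  mixed with 0.5 × the mean of their neighbors' latents (neighboring
  observables then correlate, r ≈ 0.09 vs ≈ 0.006 for random pairs), each
  protein *observes* its own latent plus Gaussian noise (sd 1.0), and the
  interaction *target* is the neighborhood-mean latent (own + neighbors).
  The signal that drives interactions is therefore spread across the
  neighborhood and can only be recovered by pooling neighbor features over
  the graph — the literal meaning of "localizes on the network". An isolated
  node's target is its own latent, so its observable is own latent + noise.
  In *iid* mode target = own latent and the graph carries no information.
  An earlier design in which the observable equalled the target plus noise
  was measured and rejected: it leaves a graph-aware scorer less than 0.01
  MicroAUC_p above a graph-blind one (best over blend weights, 3 seeds),
  because the own observable already contains the full target.
* **Link function**: positives are re-sampled without replacement with
  weight exp(slope × cos(z_d, target_p)) — strictly increasing in the
  generative cosine. The slope (15.75) is set by bisection so the
  Bayes-optimal scorer (the generative cosine itself) reaches
  MicroAUC_p ≈ 0.90. A bounded logistic link cannot reach that regime at
  these conditions: it saturates on the half of the grid with positive
  cosine and spreads positives uniformly there, capping the Bayes score near
  0.78 for any slope.

What passing tests on this generator do **not** show: the generator has no
chemistry, no sequence information, no score-distribution realism, and its
localization is planted by construction — results establish that the method
behaves as designed under the stated structure, not that it reaches any
particular performance on real databases.

## Problem sizes and numerical choices

The reference study conditions (500 × 100, 4000 links, 64-dim) keep every
experiment on one CPU: the full localization protocol (5 seeds × 2 modes ×
2 architectures, one fold each) runs in ~3–4 minutes; the 10-seed baseline
bias demonstration in seconds. Degenerate inputs are defined rather than
fatal where a sound definition exists (zero-vector cosine = 0, empty
neighborhood = zero aggregate, imputed single-class entities) and errors
where silence would mislead (single-class MacroAUC, empty alignment, k-sweep
on a protein split, non-finite training loss). Checkpoints round-trip all
parameters bit-exactly with a version tag.

## Known limitations

* The contrastive-pretraining variant of the half-twin scorer is not
  implemented; the pair scorer trains directly on the weighted
  cross-entropy. (The two objectives coincide in what they rank, not in
  calibration.)
* The trained model realizes roughly half of the Bayes headroom on localized
  data (MicroAUC_p ≈ 0.67 vs a 0.90 oracle at default noise): cold-start
  generalization from ~300 training proteins is estimation-limited, and the
  graph-vs-pruned comparison, not absolute performance, is the designed
  endpoint.
* `micro_auc` averages over test-fold entities only; whether to average over
  all entities is a judgment call, and the chosen variant is the only one in
  which every per-entity score comes from honest (held-out) predictions.
* The degree-uniform baseline band (0.45–0.55) and all calibrated constants
  are specific to the default problem size; other sizes re-run the
  calibrators (`calibrate_hub_skew`, `calibrate_link_slope`).
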