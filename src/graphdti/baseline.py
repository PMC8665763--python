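"""The degree-based naive predictor P_k.

Public DTI datasets concentrate interactions on a few hub proteins, so a
predictor that knows nothing about biology can score well: rank proteins by
their number of known drug interactors in the training data and predict, for
*every* drug, an interaction with the top k proteins. Because the prediction
ignores the drug entirely, any performance above chance measures dataset bias
rather than biological signal — which is exactly what this baseline is for.

P_k requires per-protein interaction counts from training, so it is defined
for pair and drug splits but *not* for a protein split (the test proteins'
counts are unknown by construction); :func:`naive_predict` enforces this at
the split level by never seeing one, and the CV driver raises for protein
splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import DTIMatrix, PredictionSet

logger = logging.getLogger(__name__)


@dataclass
class DegreeRanking:
    """Proteins ordered descending by training interaction count f(p);
    ties broken by lexicographic protein id."""

    protein_order: list[str]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        keys = [(-self.counts.get(p, 0), p) for p in self.protein_order]
        if keys != sorted(keys):
            raise ValueError("ordering inconsistent with counts / tie rule")

    def top_k(self, k: int) -> set[str]:
        return set(self.protein_order[:k])


def rank_proteins_by_degree(train: DTIMatrix) -> DegreeRanking:
    """f(p) = column sum of the training interaction matrix; descending sort."""
    if train.n_positives == 0 and train.n_proteins == 0:
        raise ValueError("empty training DTI matrix")
    counts = train.protein_interaction_counts()
    order = sorted(counts, key=lambda p: (-counts[p], p))
    return DegreeRanking(order, counts)


def naive_predict(
    ranking: DegreeRanking,
    k: int,
    drugs: Sequence[str],
    proteins: Sequence[str],
    labels: dict[tuple[str, str], int] | set[tuple[str, str]] | None = None,
    graded: bool = False,
) -> PredictionSet:
    """Score 1 for the top-k ranked proteins, 0 otherwise — for every drug.

    Proteins absent from the ranking count as 0 interactions (rank last).
    ``labels`` (a positive-pair set or pair->label map) fills the label
    column; omitted labels default to 0. ``graded=True`` replaces the 0/1
    scores with 1 − rank/|P| (a smoother curve for plotting; not the
    baseline's definition, which is the k-threshold predictor).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(proteins):
        logger.warning("k=%d exceeds %d proteins; clamped", k, len(proteins))
        k = len(proteins)
    known = set(ranking.protein_order)
    ranked = [p for p in ranking.protein_order if p in set(proteins)]
    unseen = sorted(p for p in proteins if p not in known)
    full_order = ranked + unseen
    if graded:
        n = max(len(full_order), 1)
        prot_score = {p: 1.0 - i / n for i, p in enumerate(full_order)}
    else:
        top = set(full_order[:k])
        prot_score = {p: (1.0 if p in top else 0.0) for p in proteins}

    n = len(drugs) * len(proteins)
    drug_col = np.repeat(np.asarray(list(drugs), dtype=object), len(proteins))
    prot_col = np.tile(np.asarray(list(proteins), dtype=object), len(drugs))
    scores = np.tile(np.asarray([prot_score[p] for p in proteins]), len(drugs))
    if labels is None:
        lab = np.zeros(n, dtype=np.int64)
    elif isinstance(labels, set):
        lab = np.fromiter(
            ((d, p) in labels for d, p in zip(drug_col, prot_col)), dtype=np.int64, count=n
        )
    else:
        lab = np.fromiter(
            (labels.get((d, p), 0) for d, p in zip(drug_col, prot_col)), dtype=np.int64, count=n
        )
    return PredictionSet(drug_col, prot_col, lab, scores)


def sweep_k(
    train: DTIMatrix,
    eval_drugs: Sequence[str],
    eval_proteins: Sequence[str],
    eval_positives: set[tuple[str, str]],
    k_grid: str = "all",
) -> tuple[int, float, list[tuple[int, float]]]:
    """Evaluate P_k over a grid of k and return (best_k, best_auc, curve).

    ``k_grid='all'`` sweeps every k in 0..|P|; ``'boundaries'`` only the k at
    which the training interaction count changes (plus 0 and |P|). The best k
    is the smallest k attaining the maximum MacroAUC.
    """
    ranking = rank_proteins_by_degree(train)
    n_p = len(eval_proteins)
    if k_grid == "all":
        ks = list(range(n_p + 1))
    elif k_grid == "boundaries":
        in_eval = [p for p in ranking.protein_order if p in set(eval_proteins)]
        counts = [ranking.counts.get(p, 0) for p in in_eval]
        ks = [0]
        for i in range(1, len(counts)):
            if counts[i] != counts[i - 1]:
                ks.append(i)
        ks.append(n_p)
        ks = sorted(set(ks))
    else:
        raise ValueError(f"unknown k_grid {k_grid!r}")

    # binary scores make the ROC a single interior point, so the trapezoidal
    # MacroAUC reduces to (1 + TPR_k - FPR_k) / 2; computed for every k at
    # once from cumulative per-protein label counts (identical to running
    # macro_auc on the thresholded predictions, asserted in the test suite)
    known = set(ranking.protein_order)
    ranked = [p for p in ranking.protein_order if p in set(eval_proteins)]
    unseen = sorted(p for p in eval_proteins if p not in known)
    full_order = ranked + unseen
    pos_per_prot = {p: 0 for p in eval_proteins}
    for d, p in eval_positives:
        if p in pos_per_prot:
            pos_per_prot[p] += 1
    n_drugs = len(eval_drugs)
    pos_by_rank = np.asarray([pos_per_prot[p] for p in full_order], dtype=np.float64)
    neg_by_rank = n_drugs - pos_by_rank
    n_pos, n_neg = pos_by_rank.sum(), neg_by_rank.sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("evaluation pairs are single-class")
    tpr = np.concatenate([[0.0], np.cumsum(pos_by_rank)]) / n_pos
    fpr = np.concatenate([[0.0], np.cumsum(neg_by_rank)]) / n_neg
    auc_all = (1.0 + tpr - fpr) / 2.0
    curve = [(k, float(auc_all[k])) for k in ks]
    best_i = int(np.argmax([a for _, a in curve]))
    best_k, best_auc = curve[best_i]
    return best_k, float(best_auc), curve


def sweep_k_cv(dti: DTIMatrix, plan) -> list[tuple[int, float]]:
    """Run the k-sweep once per CV rotation; train counts come only from the
    training folds of each rotation.

    Not applicable under a protein split: the per-protein interaction counts
    of held-out proteins are unknown by construction.
    """
    from .evaluation import fold_pairs

    if plan.scheme == "protein":
        raise ValueError(
            "the naive degree predictor is undefined under a protein split: "
            "held-out proteins have no training interaction counts"
        )
    results = []
    for f in range(plan.n_folds):
        fp = fold_pairs(dti, plan, f)
        d_tr, p_tr, y_tr = fp.train
        drugs = np.asarray(dti.drug_ids, dtype=object)
        prots = np.asarray(dti.protein_ids, dtype=object)
        train_pos = {
            (drugs[d], prots[p]) for d, p, y in zip(d_tr, p_tr, y_tr) if y == 1
        }
        train_dti = DTIMatrix(list(dti.drug_ids), list(dti.protein_ids), train_pos)
        d_te, p_te, y_te = fp.test
        test_pos = {(drugs[d], prots[p]) for d, p, y in zip(d_te, p_te, y_te) if y == 1}
        eval_drugs = sorted({drugs[d] for d in d_te})
        eval_prots = sorted({prots[p] for p in p_te})
        # pair-scheme test sets are not full grids; evaluate on the exact test pairs
        if plan.scheme == "pair":
            ranking = rank_proteins_by_degree(train_dti)
            best_k, best_auc = _sweep_on_pairs(ranking, d_te, p_te, y_te, drugs, prots)
        else:
            best_k, best_auc, _ = sweep_k(train_dti, eval_drugs, eval_prots, test_pos)
        results.append((best_k, best_auc))
    return results


def _sweep_on_pairs(ranking, d_idx, p_idx, labels, drugs, prots):
    """k-sweep where the evaluation set is an arbitrary list of pairs.

    Same cumulative-count closed form as :func:`sweep_k` (binary predictor:
    MacroAUC_k = (1 + TPR_k - FPR_k)/2), evaluated over the ranked protein list.
    """
    if labels.min() == labels.max():
        raise ValueError("evaluation pairs are single-class")
    eval_prot_ids = [prots[p] for p in p_idx]
    rank_pos = {p: i for i, p in enumerate(ranking.protein_order)}
    n_rank = len(ranking.protein_order)
    pair_rank = np.asarray([rank_pos.get(p, n_rank) for p in eval_prot_ids])
    labels = np.asarray(labels, dtype=np.float64)
    pos_by_rank = np.bincount(pair_rank, weights=labels, minlength=n_rank + 1)
    neg_by_rank = np.bincount(pair_rank, weights=1.0 - labels, minlength=n_rank + 1)
    tpr = np.concatenate([[0.0], np.cumsum(pos_by_rank)]) / labels.sum()
    fpr = np.concatenate([[0.0], np.cumsum(neg_by_rank)]) / (1.0 - labels).sum()
    auc_all = (1.0 + tpr - fpr) / 2.0
    best_k = int(np.argmax(auc_all))
    return best_k, float(auc_all[best_k])
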