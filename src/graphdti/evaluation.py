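"""Splitting schemes and bias-aware performance metrics.

Cross-validation can split over drug-protein *pairs*, over *drugs*, or over
*proteins*. Only the entity-level schemes guarantee that unseen entities
appear at evaluation time; the protein split is the cold-start regime in
which a model must score drugs against proteins it never saw labels for.

Two AUROC flavors are reported:

* **MacroAUC** — one ROC curve over all pooled pairs (equivalently the
  Mann-Whitney probability with half-credit for ties).
* **MicroAUC_p / MicroAUC_d** — the unweighted mean of per-protein
  (per-drug) AUROCs. Entities whose pairs are single-class (e.g. a protein
  with no positives) have no defined AUROC; rather than omitting them we
  impute the accuracy of thresholded predictions on their pairs, since
  omission silently drops exactly the entities the cold-start question is
  about. The unimputed variant (entities omitted) is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .datatypes import DTIMatrix, PredictionSet

Scheme = Literal["pair", "drug", "protein"]


@dataclass
class SplitPlan:
    """Fold assignment of split units (pairs, drug ids or protein ids)."""

    scheme: Scheme
    n_folds: int
    fold_of: dict  # unit -> fold index
    seed: int

    def units_in_fold(self, fold: int) -> list:
        return [u for u, f in self.fold_of.items() if f == fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.fold_of.values():
            sizes[f] += 1
        return sizes

    # -- serialization (bit-exact round trip) -------------------------------
    def to_json(self) -> str:
        units = [[list(u) if isinstance(u, tuple) else u, f] for u, f in self.fold_of.items()]
        return json.dumps(
            {"scheme": self.scheme, "n_folds": self.n_folds, "seed": self.seed, "units": units}
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        obj = json.loads(text)
        fold_of = {
            (tuple(u) if isinstance(u, list) else u): f for u, f in obj["units"]
        }
        return cls(obj["scheme"], obj["n_folds"], fold_of, obj["seed"])


def make_split(dti: DTIMatrix, scheme: Scheme, n_folds: int, seed: int) -> SplitPlan:
    """Shuffle the split units (seeded) and deal them into near-equal folds.

    Pair scheme: units are all |D| x |P| grid cells. Drug/protein schemes:
    units are the entity ids; every pair (d, p) then belongs to the fold of
    its drug / protein.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if scheme == "protein":
        units: list = list(dti.protein_ids)
    elif scheme == "drug":
        units = list(dti.drug_ids)
    elif scheme == "pair":
        units = [(d, p) for d in dti.drug_ids for p in dti.protein_ids]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(units) < n_folds:
        raise ValueError(f"{len(units)} {scheme} units cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    fold_of = {units[int(i)]: int(k % n_folds) for k, i in enumerate(order)}
    return SplitPlan(scheme, n_folds, fold_of, seed)


@dataclass
class FoldPairs:
    """Index arrays (into an EntityIndex) for one CV rotation."""

    train: tuple[np.ndarray, np.ndarray, np.ndarray]  # (drug_idx, prot_idx, label)
    val: tuple[np.ndarray, np.ndarray, np.ndarray]
    test: tuple[np.ndarray, np.ndarray, np.ndarray]


def fold_pairs(dti: DTIMatrix, plan: SplitPlan, test_fold: int) -> FoldPairs:
    """Materialize train/validation/test pair sets for one rotation.

    With >= 3 folds: test = ``test_fold``, validation = the next fold
    (cyclically), train = the rest. With exactly 2 folds the non-test fold is
    split 4:1 into train and validation (a plain test/validation rotation
    would leave no training units).
    """
    M = dti.to_dense()
    n_d, n_p = M.shape
    drug_pos = {d: i for i, d in enumerate(dti.drug_ids)}
    prot_pos = {p: i for i, p in enumerate(dti.protein_ids)}

    def grid(drug_sel: np.ndarray, prot_sel: np.ndarray):
        di, pi = np.meshgrid(drug_sel, prot_sel, indexing="ij")
        di, pi = di.reshape(-1), pi.reshape(-1)
        return di, pi, M[di, pi].astype(np.int64)

    if plan.scheme in ("protein", "drug"):
        pos = prot_pos if plan.scheme == "protein" else drug_pos
        fold_units: list[list[int]] = [[] for _ in range(plan.n_folds)]
        for u, f in plan.fold_of.items():
            fold_units[f].append(pos[u])
        for f in range(plan.n_folds):
            fold_units[f] = sorted(fold_units[f])
        test_units = np.asarray(fold_units[test_fold], dtype=np.intp)
        if plan.n_folds >= 3:
            val_fold = (test_fold + 1) % plan.n_folds
            val_units = np.asarray(fold_units[val_fold], dtype=np.intp)
            train_units = np.asarray(
                sorted(
                    u
                    for f in range(plan.n_folds)
                    if f not in (test_fold, val_fold)
                    for u in fold_units[f]
                ),
                dtype=np.intp,
            )
        else:
            rest = fold_units[1 - test_fold]
            n_val = max(1, len(rest) // 5)
            val_units = np.asarray(rest[:n_val], dtype=np.intp)
            train_units = np.asarray(rest[n_val:], dtype=np.intp)
        if plan.scheme == "protein":
            drugs_all = np.arange(n_d, dtype=np.intp)
            return FoldPairs(
                train=grid(drugs_all, train_units),
                val=grid(drugs_all, val_units),
                test=grid(drugs_all, test_units),
            )
        prots_all = np.arange(n_p, dtype=np.intp)
        return FoldPairs(
            train=grid(train_units, prots_all),
            val=grid(val_units, prots_all),
            test=grid(test_units, prots_all),
        )

    # pair scheme
    fold_cells: list[list[tuple[int, int]]] = [[] for _ in range(plan.n_folds)]
    for (d, p), f in plan.fold_of.items():
        fold_cells[f].append((drug_pos[d], prot_pos[p]))

    def cells_to_arrays(cells: list[tuple[int, int]]):
        cells = sorted(cells)
        di = np.asarray([c[0] for c in cells], dtype=np.intp)
        pi = np.asarray([c[1] for c in cells], dtype=np.intp)
        return di, pi, M[di, pi].astype(np.int64)

    if plan.n_folds >= 3:
        val_fold = (test_fold + 1) % plan.n_folds
        train_cells = [
            c for f in range(plan.n_folds) if f not in (test_fold, val_fold) for c in fold_cells[f]
        ]
        val_cells = fold_cells[val_fold]
    else:
        rest = sorted(fold_cells[1 - test_fold])
        n_val = max(1, len(rest) // 5)
        val_cells, train_cells = rest[:n_val], rest[n_val:]
    return FoldPairs(
        train=cells_to_arrays(train_cells),
        val=cells_to_arrays(val_cells),
        test=cells_to_arrays(fold_cells[test_fold]),
    )


# ---------------------------------------------------------------------------
# AUROC metrics


def macro_auc(predictions: PredictionSet) -> float:
    """AUROC over all pooled pairs (trapezoidal; ties get half credit).

    Raises on single-class input — imputation is a micro-average concept and
    deliberately does not apply here.
    """
    labels, scores = predictions.labels, predictions.scores
    if len(labels) == 0 or labels.min() == labels.max():
        raise ValueError("MacroAUC needs at least one positive and one negative pair")
    return float(roc_auc_score(labels, scores))


def _accuracy(labels: np.ndarray, scores: np.ndarray, threshold: float) -> float:
    predicted = (scores >= threshold).astype(np.int64)
    return float(np.mean(predicted == labels))


def _auc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUROC with average-rank tie handling (equals the
    trapezoidal ROC area). Used per entity; avoids per-call overhead."""
    r = stats.rankdata(scores, method="average")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def micro_auc(
    predictions: PredictionSet,
    axis: Literal["protein", "drug"] = "protein",
    impute: bool = True,
    threshold: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """Unweighted mean of per-entity AUROCs along the given axis.

    Entities whose pairs are single-class have no defined AUROC; with
    ``impute=True`` they contribute the accuracy of scores thresholded at
    ``threshold``; with ``impute=False`` they are omitted (the unimputed
    variant). Returns (mean, per-entity table with columns entity_id, n_pos,
    n_neg, auc, imputed).
    """
    key = predictions.protein_ids if axis == "protein" else predictions.drug_ids
    if len(key) == 0:
        raise ValueError("empty prediction set")
    order = np.argsort(key.astype(str), kind="stable")
    key_s = key[order]
    labels_s = predictions.labels[order]
    scores_s = predictions.scores[order]
    boundaries = np.flatnonzero(key_s[1:] != key_s[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(key_s)]])

    rows = []
    for s, e in zip(starts, ends):
        ent = key_s[s]
        lab, sco = labels_s[s:e], scores_s[s:e]
        n_pos, n_neg = int(lab.sum()), int((1 - lab).sum())
        if n_pos > 0 and n_neg > 0:
            rows.append((ent, n_pos, n_neg, _auc_rank(lab, sco), False))
        else:
            rows.append((ent, n_pos, n_neg, _accuracy(lab, sco, threshold), True))
    table = pd.DataFrame(rows, columns=["entity_id", "n_pos", "n_neg", "auc", "imputed"])
    if impute:
        value = float(table["auc"].mean())
    else:
        defined = table.loc[~table["imputed"], "auc"]
        value = float(defined.mean()) if len(defined) else float("nan")
    return value, table


@dataclass
class MetricReport:
    """Headline metrics for one evaluation set."""

    macro_auc: float
    micro_auc_p: float
    micro_auc_d: float
    micro_auc_p_unimputed: float
    per_protein: pd.DataFrame = field(repr=False)
    per_drug: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "macro_auc": self.macro_auc,
            "micro_auc_p": self.micro_auc_p,
            "micro_auc_d": self.micro_auc_d,
            "micro_auc_p_unimputed": self.micro_auc_p_unimputed,
        }

    def write(self, json_path=None, per_protein_path=None, per_drug_path=None) -> None:
        if json_path is not None:
            with open(json_path, "wt") as fh:
                json.dump(self.to_dict(), fh, indent=2)
        if per_protein_path is not None:
            self.per_protein.to_csv(per_protein_path, sep="\t", index=False)
        if per_drug_path is not None:
            self.per_drug.to_csv(per_drug_path, sep="\t", index=False)


def evaluate_predictions(predictions: PredictionSet, threshold: float = 0.5) -> MetricReport:
    """All headline metrics for one PredictionSet."""
    mp, per_p = micro_auc(predictions, axis="protein", impute=True, threshold=threshold)
    mp_u, _ = micro_auc(predictions, axis="protein", impute=False, threshold=threshold)
    md, per_d = micro_auc(predictions, axis="drug", impute=True, threshold=threshold)
    return MetricReport(
        macro_auc=macro_auc(predictions),
        micro_auc_p=mp,
        micro_auc_d=md,
        micro_auc_p_unimputed=mp_u,
        per_protein=per_p,
        per_drug=per_d,
    )


# ---------------------------------------------------------------------------
# Cross-method significance testing


@dataclass
class ComparisonResult:
    t_statistic: float
    p_value: float        # one-sided, H1: mean(a) > mean(b)
    p_adjusted: float     # Bonferroni
    n_comparisons: int
    degenerate: bool = False


def compare_models(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    n_comparisons: int = 1,
    paired: bool = False,
) -> ComparisonResult:
    """One-sided t-test of mean(a) > mean(b) with Bonferroni correction.

    Welch (unequal-variance) by default; ``paired=True`` switches to a paired
    test across folds. Zero variance in both samples with equal means is
    flagged and reported as p = 0.5 by convention.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two folds per method")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return ComparisonResult(0.0, 0.5, min(1.0, n_comparisons * 0.5), n_comparisons, True)
    if paired:
        res = stats.ttest_rel(a, b, alternative="greater")
    else:
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    p = float(res.pvalue)
    return ComparisonResult(
        float(res.statistic), p, min(1.0, n_comparisons * p), n_comparisons
    )
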