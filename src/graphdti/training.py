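"""Loss, class-imbalance weighting, and the end-to-end training loop.

The full model is: per-side feature transformation (affine + LeakyReLU),
optional residual graph-convolution stack over the protein side, and the
half-twin cosine scorer. Known interactions are a tiny fraction of the
drug x protein grid, so positives are up-weighted in the binary cross-entropy
by ``w = |D| * |P| / |Int|`` computed from the *training* fold (using the full
dataset's counts would leak test-set information).

Training is full-batch by default — the propagation stack runs once per
optimization step and all training pairs are scored against it — with an
optional per-epoch negative subsample for the training pairs only; the
validation and test paths score every pair and have no sampler. Model
selection is by early stopping on the validation fold's protein-centric
micro-averaged AUROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .datatypes import DTIMatrix, FeatureTable, InteractionGraph, PredictionSet
from .evaluation import FoldPairs, micro_auc
from .features import FeatureTransform, HalfTwinScorer, TransformConfig
from .propagation import PropagationStack, build_edge_arrays

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class LossConfig:
    positive_weight: float = 1.0
    weighting_mode: Literal["positive_term", "both_terms"] = "positive_term"

    def __post_init__(self) -> None:
        if not np.isfinite(self.positive_weight) or self.positive_weight < 1:
            raise ValueError("positive_weight must be finite and >= 1")
        if self.weighting_mode not in ("positive_term", "both_terms"):
            raise ValueError(f"unknown weighting_mode {self.weighting_mode!r}")


def compute_positive_weight(n_drugs: int, n_proteins: int, n_links: int) -> float:
    """Imbalance ratio w = |D| * |P| / |Int|."""
    if n_links < 1:
        raise ValueError("positive weight undefined for zero interaction links")
    return n_drugs * n_proteins / n_links


SCORE_CLAMP = 1e-7


def _bce_terms(scores: np.ndarray, labels: np.ndarray, w: float, mode: str) -> np.ndarray:
    x = np.clip(scores, SCORE_CLAMP, 1.0 - SCORE_CLAMP)
    y = labels
    if mode == "positive_term":
        return -(w * y * np.log(x) + (1 - y) * np.log(1 - x))
    return -w * (y * np.log(x) + (1 - y) * np.log(1 - x))


def weighted_bce(predictions: PredictionSet, config: LossConfig) -> float:
    """Mean weighted binary cross-entropy over all pairs.

    ``positive_term`` multiplies only the positive-label term by w (weighting
    positive samples); ``both_terms`` multiplies the whole per-pair loss by w.
    """
    if len(predictions) == 0:
        raise ValueError("empty pair set")
    return float(
        np.mean(
            _bce_terms(
                predictions.scores,
                predictions.labels.astype(np.float64),
                config.positive_weight,
                config.weighting_mode,
            )
        )
    )


def weighted_bce_tensor(scores: Tensor, labels: np.ndarray, w: float, mode: str) -> Tensor:
    """Differentiable weighted BCE on an autodiff score tensor."""
    y = np.asarray(labels, dtype=np.float64)
    x = ad.clip(scores, SCORE_CLAMP, 1.0 - SCORE_CLAMP)
    if mode == "positive_term":
        per_pair = -(Tensor(w * y) * ad.log(x) + Tensor(1.0 - y) * ad.log(1.0 - x))
    else:
        per_pair = Tensor(-w) * (Tensor(y) * ad.log(x) + Tensor(1.0 - y) * ad.log(1.0 - x))
    return ad.tmean(per_pair)


# ---------------------------------------------------------------------------
# Model


@dataclass(frozen=True)
class ModelConfig:
    arch: Literal["graph", "pruned", "nograph"] = "graph"
    embed_dim: int = 64
    stack_height: int = 3
    agg: str = "softmax"
    activation: str = "ReLU"
    leaky_slope: float = 0.01
    weighted_edges: bool = False

    def __post_init__(self) -> None:
        if self.arch not in ("graph", "pruned", "nograph"):
            raise ValueError(f"unknown arch {self.arch!r}")


@dataclass
class ModelData:
    """Aligned numeric views of one dataset (rows follow the entity index)."""

    graph: InteractionGraph
    drug_ids: list[str]
    protein_ids: list[str]
    Xd: np.ndarray  # (n_drugs, drug_feature_dim)
    Xp: np.ndarray  # (n_proteins, protein_feature_dim)

    @classmethod
    def from_tables(
        cls,
        graph: InteractionGraph,
        dti: DTIMatrix,
        protein_features: FeatureTable,
        drug_features: FeatureTable,
    ) -> "ModelData":
        if list(protein_features.entity_ids) != list(graph.node_ids) or list(
            dti.protein_ids
        ) != list(graph.node_ids):
            raise ValueError("protein tables are not aligned with graph nodes")
        if list(drug_features.entity_ids) != list(dti.drug_ids):
            raise ValueError("drug feature rows are not aligned with the DTI drug list")
        return cls(
            graph,
            list(dti.drug_ids),
            list(dti.protein_ids),
            drug_features.vectors,
            protein_features.vectors,
        )


def _orthogonal(n_in: int, n_out: int, rng: np.random.Generator) -> np.ndarray:
    """Semi-orthogonal matrix (orthonormal rows or columns) of shape (n_in, n_out)."""
    q, _ = np.linalg.qr(rng.normal(size=(max(n_in, n_out), min(n_in, n_out))))
    return q if n_in >= n_out else q.T


class DTIModel:
    """Feature transforms + optional propagation stack + half-twin scorer."""

    def __init__(
        self,
        prot_in_dim: int,
        drug_in_dim: int,
        config: ModelConfig = ModelConfig(),
        seed: int = 0,
    ):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.embed_dim
        self.prot_transform = FeatureTransform(
            TransformConfig(prot_in_dim, d, "LeakyReLU", config.leaky_slope), rng
        )
        self.drug_transform = FeatureTransform(
            TransformConfig(drug_in_dim, d, "LeakyReLU", config.leaky_slope), rng
        )
        # semi-orthogonal initialization: an orthogonal map preserves cosines,
        # so the scorer starts from an undistorted similarity space
        self.prot_transform.W.data = _orthogonal(prot_in_dim, d, rng)
        if prot_in_dim == drug_in_dim:
            # shared-rotation initialization: both branches start as the same
            # map, so drug/protein cosines are aligned from the first epoch;
            # the branches remain free to diverge during training
            self.drug_transform.W.data = self.prot_transform.W.data.copy()
        else:
            self.drug_transform.W.data = _orthogonal(drug_in_dim, d, rng)
        if config.arch == "nograph":
            self.stack = None
        else:
            self.stack = PropagationStack(
                d,
                height=config.stack_height,
                rng=rng,
                agg=config.agg,  # ignored by pruned blocks
                activation=config.activation,
                use_graph=(config.arch == "graph"),
            )
        self.scorer = HalfTwinScorer()

    def parameters(self) -> list[Tensor]:
        ps = self.prot_transform.parameters() + self.drug_transform.parameters()
        if self.stack is not None:
            ps += self.stack.parameters()
        return ps + self.scorer.parameters()

    def protein_embeddings(self, Xp: np.ndarray, edges) -> Tensor:
        P = self.prot_transform.forward(Tensor(Xp))
        if self.stack is None:
            return P
        if self.config.arch == "graph":
            src, dst, w = edges
            return self.stack.forward(P, src, dst, w)
        return self.stack.forward(P, None, None, None)

    def forward_scores(
        self, data: ModelData, edges, d_idx: np.ndarray, p_idx: np.ndarray
    ) -> Tensor:
        P = self.protein_embeddings(data.Xp, edges)
        U = self.drug_transform.forward(Tensor(data.Xd))
        return self.scorer.forward(ad.gather(U, d_idx), ad.gather(P, p_idx))

    def predict(self, data: ModelData, d_idx: np.ndarray, p_idx: np.ndarray) -> np.ndarray:
        """Scores for pairs; the evaluation path — no sampling of any kind."""
        edges = self._edges(data)
        return self.forward_scores(data, edges, d_idx, p_idx).data

    def _edges(self, data: ModelData):
        if self.config.arch != "graph":
            return None
        return build_edge_arrays(data.graph, weighted=self.config.weighted_edges)

    # -- checkpointing -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i:04d}": p.data for i, p in enumerate(self.parameters())}

    def save(self, path) -> None:
        meta = json.dumps(
            {"version": CHECKPOINT_VERSION, "config": self.config.__dict__}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as zf:
            meta = json.loads(bytes(zf["__meta__"]).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            params = self.parameters()
            for i, p in enumerate(params):
                arr = zf[f"param_{i:04d}"]
                if arr.shape != p.data.shape:
                    raise ValueError(f"checkpoint shape mismatch at parameter {i}")
                p.data = arr.copy()


# ---------------------------------------------------------------------------
# Training loop


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.

    ``feature_jitter_sd`` adds fresh Gaussian noise to the protein features at
    every training epoch (training forward passes only; validation and test
    always see the clean features). Cold-start generalization is limited by
    the model memorizing training proteins through their exact feature
    vectors — the cosine scorer is scale-invariant, so weight decay cannot
    prevent this — and denoising jitter is the regularizer that directly
    breaks that lookup.
    """

    learning_rate: float = 3e-2
    max_epochs: int = 300
    patience: int = 30
    feature_jitter_sd: float = 2.0
    negative_subsample_ratio: float | None = None  # training pairs only
    drug_batch_size: int | None = None  # None: all drugs in one step per epoch
    weighting_mode: Literal["positive_term", "both_terms"] = "positive_term"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.negative_subsample_ratio is not None and self.negative_subsample_ratio <= 0:
            raise ValueError("negative_subsample_ratio must be None or > 0")
        if self.feature_jitter_sd < 0:
            raise ValueError("feature_jitter_sd must be >= 0")


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainedModel:
    model: DTIModel
    history: pd.DataFrame  # columns: epoch, train_loss, val_metric
    best_epoch: int
    positive_weight: float

    def write_history(self, path) -> None:
        self.history.to_csv(path, sep="\t", index=False)


def _snapshot(params: list[Tensor]) -> list[np.ndarray]:
    return [p.data.copy() for p in params]


def _restore(params: list[Tensor], snap: list[np.ndarray]) -> None:
    for p, s in zip(params, snap):
        p.data = s.copy()


def train_model(
    data: ModelData,
    fold: FoldPairs,
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Train transforms + stack + scorer jointly on one CV rotation.

    Minimizes the weighted cross-entropy on the training pairs (optionally
    negative-subsampled per epoch); tracks the protein-centric micro-averaged
    AUROC on *all* validation pairs; stops when the validation metric fails
    to improve for ``patience`` epochs and returns the best-epoch parameters.
    Deterministic given the seeds in the configs.
    """
    d_tr, p_tr, y_tr = fold.train
    if len(y_tr) == 0:
        raise ValueError("empty training pair set")
    w = compute_positive_weight(
        len(np.unique(d_tr)), len(np.unique(p_tr)), int(y_tr.sum())
    )
    model = DTIModel(data.Xp.shape[1], data.Xd.shape[1], model_config, seed=train_config.seed)
    params = model.parameters()
    opt = Adam(params, lr=train_config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed).spawn(1)[0])
    edges = model._edges(data)

    d_val, p_val, y_val = fold.val
    val_prot = np.asarray(data.protein_ids, dtype=object)[p_val]
    val_drug = np.asarray(data.drug_ids, dtype=object)[d_val]

    history: list[tuple[int, float, float]] = []
    best_metric, best_epoch, best_snap = -np.inf, -1, _snapshot(params)
    since_best = 0

    Xp_clean = data.Xp
    for epoch in range(train_config.max_epochs):
        di, pi, yi = d_tr, p_tr, y_tr
        if train_config.negative_subsample_ratio is not None:
            pos = np.flatnonzero(yi == 1)
            neg = np.flatnonzero(yi == 0)
            n_neg = min(len(neg), int(round(train_config.negative_subsample_ratio * len(pos))))
            keep = np.concatenate([pos, rng.choice(neg, size=n_neg, replace=False)])
            keep.sort()
            di, pi, yi = di[keep], pi[keep], yi[keep]

        if train_config.drug_batch_size is None:
            batches = [np.arange(len(yi))]
        else:
            drug_order = rng.permutation(np.unique(di))
            batches = []
            for start in range(0, len(drug_order), train_config.drug_batch_size):
                sel = np.isin(di, drug_order[start : start + train_config.drug_batch_size])
                batches.append(np.flatnonzero(sel))

        if train_config.feature_jitter_sd > 0:
            data.Xp = Xp_clean + train_config.feature_jitter_sd * rng.normal(
                size=Xp_clean.shape
            )
        epoch_loss, n_pairs = 0.0, 0
        for batch in batches:
            if len(batch) == 0:
                continue
            opt.zero_grad()
            scores = model.forward_scores(data, edges, di[batch], pi[batch])
            loss = weighted_bce_tensor(scores, yi[batch], w, train_config.weighting_mode)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch of {len(batch)} pairs; "
                    f"max |param| = {max(np.abs(p.data).max() for p in params):.3g}"
                )
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
            n_pairs += len(batch)
        epoch_loss /= max(n_pairs, 1)

        data.Xp = Xp_clean  # validation always sees clean features
        val_scores = model.predict(data, d_val, p_val)
        val_pred = PredictionSet(val_drug, val_prot, y_val, val_scores)
        val_metric, _ = micro_auc(val_pred, axis="protein", impute=True)
        history.append((epoch, epoch_loss, val_metric))

        if val_metric > best_metric:
            best_metric, best_epoch = val_metric, epoch
            best_snap = _snapshot(params)
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_config.patience:
                break

    _restore(params, best_snap)
    return TrainedModel(
        model,
        pd.DataFrame(history, columns=["epoch", "train_loss", "val_metric"]),
        best_epoch,
        w,
    )


def predictions_for(
    trained: TrainedModel, data: ModelData, pairs: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> PredictionSet:
    """Score a pair set (e.g. the test fold) with a trained model."""
    d_idx, p_idx, labels = pairs
    scores = trained.model.predict(data, d_idx, p_idx)
    return PredictionSet(
        np.asarray(data.drug_ids, dtype=object)[d_idx],
        np.asarray(data.protein_ids, dtype=object)[p_idx],
        labels,
        scores,
    )
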