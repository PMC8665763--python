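"""Splitting schemes, AUROC metrics with imputation, and significance tests."""

import numpy as np
import pytest
from scipy import stats

from graphdti.datatypes import DTIMatrix, PredictionSet
from graphdti.evaluation import (
    SplitPlan,
    compare_models,
    evaluate_predictions,
    fold_pairs,
    macro_auc,
    make_split,
    micro_auc,
)


def _pred(labels, scores, drugs=None, prots=None):
    n = len(labels)
    return PredictionSet(
        np.asarray(drugs if drugs is not None else [f"d{i}" for i in range(n)], dtype=object),
        np.asarray(prots if prots is not None else ["p0"] * n, dtype=object),
        np.asarray(labels),
        np.asarray(scores, dtype=float),
    )


def _pairwise_auc_oracle(labels, scores):
    """O(n^2) Mann-Whitney probability with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestMakeSplit:
    @pytest.mark.parametrize("scheme", ["pair", "drug", "protein"])
    @pytest.mark.parametrize("seed", range(20))
    def test_folds_partition_units_with_near_equal_sizes(self, scheme, seed):
        rng = np.random.default_rng(seed)
        dti = DTIMatrix(
            [f"d{i}" for i in range(7)],
            [f"p{i}" for i in range(13)],
            {(f"d{rng.integers(7)}", f"p{rng.integers(13)}") for _ in range(20)},
        )
        plan = make_split(dti, scheme, n_folds=4, seed=seed)
        sizes = plan.fold_sizes()
        n_units = {"pair": 7 * 13, "drug": 7, "protein": 13}[scheme]
        assert sum(sizes) == n_units
        assert max(sizes) - min(sizes) <= 1
        assert set(plan.fold_of.values()) <= set(range(4))

    def test_protein_scheme_pairs_follow_their_protein(self):
        dti = DTIMatrix(
            [f"d{i}" for i in range(4)], [f"p{i}" for i in range(10)],
            {("d0", "p0"), ("d1", "p5")},
        )
        plan = make_split(dti, "protein", 5, seed=1)
        fp = fold_pairs(dti, plan, test_fold=0)
        test_prots = {dti.protein_ids[i] for i in fp.test[1]}
        train_prots = {dti.protein_ids[i] for i in fp.train[1]}
        val_prots = {dti.protein_ids[i] for i in fp.val[1]}
        assert test_prots.isdisjoint(train_prots)
        assert test_prots.isdisjoint(val_prots)
        assert val_prots.isdisjoint(train_prots)

    def test_pair_scheme_even_folds(self):
        dti = DTIMatrix(["d0", "d1"], [f"p{i}" for i in range(5)], set())
        plan = make_split(dti, "pair", 5, seed=0)
        assert plan.fold_sizes() == [2, 2, 2, 2, 2]

    def test_same_seed_reproducible_different_seed_differs(self):
        dti = DTIMatrix(
            [f"d{i}" for i in range(3)], [f"p{i}" for i in range(30)], set()
        )
        a = make_split(dti, "protein", 3, seed=5)
        b = make_split(dti, "protein", 3, seed=5)
        assert a.fold_of == b.fold_of
        assert any(
            make_split(dti, "protein", 3, seed=s).fold_of != a.fold_of for s in range(10, 20)
        )

    def test_too_few_units_raises(self):
        dti = DTIMatrix(["d0"], ["p0", "p1"], set())
        with pytest.raises(ValueError):
            make_split(dti, "protein", 5, seed=0)

    def test_serialization_round_trip_bit_exact(self):
        dti = DTIMatrix(["d0", "d1"], [f"p{i}" for i in range(6)], set())
        for scheme in ["protein", "pair"]:
            plan = make_split(dti, scheme, 3, seed=2)
            back = SplitPlan.from_json(plan.to_json())
            assert back.fold_of == plan.fold_of
            assert (back.scheme, back.n_folds, back.seed) == (scheme, 3, 2)


class TestMacroAUC:
    def test_perfect_ranking_is_one(self):
        assert macro_auc(_pred([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])) == 1.0

    def test_constant_scores_are_half(self):
        assert macro_auc(_pred([1, 0, 1, 0], [0.5] * 4)) == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            macro_auc(_pred([1, 1], [0.3, 0.4]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.integers(0, 2, size=n)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        got = macro_auc(_pred(labels, scores))
        assert got == pytest.approx(_pairwise_auc_oracle(labels, scores), abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        a = macro_auc(_pred(labels, scores))
        b = macro_auc(_pred(labels, 1 / (1 + np.exp(-7 * scores))))
        assert a == pytest.approx(b, abs=1e-12)

    def test_complement_symmetry(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.permutation(30).astype(float)  # tie-free
        a = macro_auc(_pred(labels, scores))
        b = macro_auc(_pred(labels, -scores))
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestMicroAUC:
    def test_imputed_two_protein_worked_example(self):
        # protein A perfectly ranked (AUC 1), protein B all-negative with all
        # scores below threshold (accuracy 1) -> MicroAUC_p = 1
        pred = _pred(
            [1, 0, 0, 0],
            [0.9, 0.2, 0.3, 0.1],
            drugs=["d0", "d1", "d0", "d1"],
            prots=["A", "A", "B", "B"],
        )
        value, table = micro_auc(pred, axis="protein", impute=True, threshold=0.5)
        assert value == pytest.approx(1.0)
        assert table.set_index("entity_id").loc["B", "imputed"]

    def test_imputed_equals_unimputed_when_all_entities_two_class(self, rng):
        n_d, n_p = 8, 6
        labels = rng.integers(0, 2, size=n_d * n_p)
        labels = labels.reshape(n_d, n_p)
        labels[0, :], labels[1, :] = 1, 0  # every protein sees both classes
        drugs = np.repeat([f"d{i}" for i in range(n_d)], n_p)
        prots = np.tile([f"p{j}" for j in range(n_p)], n_d)
        pred = _pred(labels.reshape(-1), rng.random(n_d * n_p), drugs, prots)
        with_imp, _ = micro_auc(pred, axis="protein", impute=True)
        without, _ = micro_auc(pred, axis="protein", impute=False)
        assert with_imp == pytest.approx(without, abs=1e-12)

    @pytest.mark.parametrize("axis", ["protein", "drug"])
    def test_matches_per_entity_loop_oracle(self, axis, rng):
        from sklearn.metrics import roc_auc_score

        n_d, n_p = 20, 30
        labels = (rng.random((n_d, n_p)) < 0.3).astype(int)
        scores = rng.random((n_d, n_p))
        drugs = np.repeat([f"d{i:02d}" for i in range(n_d)], n_p)
        prots = np.tile([f"p{j:02d}" for j in range(n_p)], n_d)
        pred = _pred(labels.reshape(-1), scores.reshape(-1), drugs, prots)
        got, _ = micro_auc(pred, axis=axis, impute=True, threshold=0.5)

        vals = []
        M = labels if axis == "drug" else labels.T
        S = scores if axis == "drug" else scores.T
        for lab, sco in zip(M, S):
            if 0 < lab.sum() < len(lab):
                vals.append(roc_auc_score(lab, sco))
            else:
                vals.append(np.mean((sco >= 0.5).astype(int) == lab))
        assert got == pytest.approx(np.mean(vals), abs=1e-9)

    def test_single_entity_micro_equals_macro(self, rng):
        labels = rng.integers(0, 2, size=25)
        labels[:2] = [0, 1]
        scores = rng.random(25)
        pred = _pred(labels, scores, prots=["pX"] * 25)
        m, _ = micro_auc(pred, axis="protein")
        assert m == pytest.approx(macro_auc(pred), abs=1e-12)

    def test_entity_with_positives_but_no_negatives_is_imputed(self):
        pred = _pred([1, 1], [0.8, 0.9], drugs=["d0", "d1"], prots=["A", "A"])
        value, table = micro_auc(pred, axis="protein", impute=True, threshold=0.5)
        assert table["imputed"].all()
        assert value == pytest.approx(1.0)  # both predicted positive, both are


class TestEvaluatePredictions:
    def test_report_fields_consistent(self, rng):
        n_d, n_p = 6, 9
        labels = (rng.random((n_d, n_p)) < 0.4).astype(int)
        labels[:, 0] = [1, 0, 1, 0, 1, 0]
        drugs = np.repeat([f"d{i}" for i in range(n_d)], n_p)
        prots = np.tile([f"p{j}" for j in range(n_p)], n_d)
        pred = _pred(labels.reshape(-1), rng.random(n_d * n_p), drugs, prots)
        rep = evaluate_predictions(pred)
        assert 0 <= rep.macro_auc <= 1
        assert 0 <= rep.micro_auc_p <= 1
        assert len(rep.per_protein) == n_p
        assert len(rep.per_drug) == n_d


class TestCompareModels:
    def test_identical_samples_give_p_half(self):
        res = compare_models([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.p_value == pytest.approx(0.5)
        assert res.degenerate

    def test_clear_separation_is_significant(self):
        a = [0.9, 0.901, 0.899]
        b = [0.1, 0.099, 0.101]
        res = compare_models(a, b)
        assert res.p_value < 0.01
        # closed-form check against scipy directly
        want = stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
        assert res.p_value == pytest.approx(float(want))

    def test_bonferroni_clamps_at_one(self):
        res = compare_models([0.5, 0.6, 0.4], [0.55, 0.45, 0.65], n_comparisons=4)
        assert res.p_adjusted == min(1.0, 4 * res.p_value)
        res2 = compare_models([0.3, 0.2], [0.8, 0.9], n_comparisons=10)
        assert res2.p_adjusted == 1.0

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            compare_models([0.5], [0.4, 0.3])
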