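import numpy as np
import pytest

from bwnet import (
    AssociationDataset,
    auc_from_scores,
    generate_synthetic,
    kfold_cv,
    loocv,
    worked_toy,
)
from bwnet.synthetic import SyntheticSpec
from tests.oracles import pairwise_auc_quadratic, trapezoid_auc


class TestAucFromScores:
    def test_hand_counted_example(self):
        assert auc_from_scores([0.9, 0.4], [0.8, 0.3, 0.1]) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert auc_from_scores([2.0, 3.0], [0.0, 1.0]) == 1.0

    def test_identical_distributions_give_half(self):
        assert auc_from_scores([1.0, 2.0], [1.0, 2.0]) == 0.5

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([], [1.0])
        with pytest.raises(ValueError):
            auc_from_scores([1.0], [])

    def test_matches_quadratic_and_trapezoid_oracles(self, rng):
        for _ in range(30):
            # integer scores force ties; floats exercise the generic case
            pos = rng.integers(0, 6, rng.integers(1, 8)).astype(float)
            neg = rng.integers(0, 6, rng.integers(1, 8)).astype(float)
            got = auc_from_scores(pos, neg)
            assert got == pytest.approx(pairwise_auc_quadratic(pos, neg), abs=1e-12)
            assert got == pytest.approx(trapezoid_auc(pos, neg), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.random(40)
        neg = rng.random(60) * 0.9
        got = auc_from_scores(pos, neg)
        ref = roc_auc_score(
            np.r_[np.ones(40), np.zeros(60)], np.concatenate([pos, neg])
        )
        assert got == pytest.approx(ref, abs=1e-12)

    def test_complement_symmetry(self, rng):
        pos = rng.integers(0, 5, 7).astype(float)
        neg = rng.integers(0, 5, 9).astype(float)
        assert auc_from_scores(pos, neg) + auc_from_scores(neg, pos) == pytest.approx(1.0)


class TestLoocv:
    def test_exactly_one_rerun_per_known_pair(self, toy):
        calls = []

        def counting(A):
            calls.append(A.copy())
            return np.ones_like(A)

        loocv(toy, score_fn=counting)
        assert len(calls) == toy.nnz
        # each call masks exactly one known pair
        for A in calls:
            assert A.sum() == toy.nnz - 1

    def test_dataset_left_intact(self, toy):
        before = toy.adjacency.copy()
        loocv(toy, score_fn=lambda A: np.ones_like(A))
        np.testing.assert_array_equal(toy.adjacency, before)

    def test_adjacency_echo_control_scores_half(self, toy):
        # a degenerate "pipeline" echoing the masked adjacency scores every
        # test pair 0, tying with all candidate pairs -> AUC exactly 0.5
        res = loocv(toy, score_fn=lambda A: A)
        assert res.auc == 0.5

    def test_perfect_scorer_gives_unit_auc(self, toy):
        res = loocv(toy, score_fn=lambda A: toy.adjacency)
        assert res.auc == 1.0
        assert all(rank == 1 for _, _, rank, _ in res.per_positive_ranks)

    def test_roc_monotone_from_origin_to_corner(self, toy):
        res = loocv(toy)
        pts = res.roc_points
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_too_few_positives_rejected(self):
        ds = AssociationDataset(["d1", "d2"], ["m1", "m2"],
                                np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValueError):
            loocv(ds)


@pytest.fixture(scope="module")
def small():
    return generate_synthetic(SyntheticSpec(8, 12, 2, 0.5, 0.05, seed=3))


class TestKfold:

    def test_bit_reproducible_given_seed(self, small):
        a = kfold_cv(small, folds=3, repeats=2, seed=11)
        b = kfold_cv(small, folds=3, repeats=2, seed=11)
        assert a.auc_per_repeat == b.auc_per_repeat
        assert a.mean_auc == b.mean_auc

    def test_different_seeds_shuffle_differently(self, small):
        a = kfold_cv(small, folds=3, repeats=1, seed=11,
                     score_fn=lambda A: A + 0.0)
        b = kfold_cv(small, folds=3, repeats=1, seed=12,
                     score_fn=lambda A: A + 0.0)
        # both are degenerate echo scorers; ranks differ only via fold makeup
        assert a.per_positive_ranks != b.per_positive_ranks

    def test_one_pair_per_fold_matches_loocv(self, toy):
        res_k = kfold_cv(toy, folds=toy.nnz, repeats=1, seed=5)
        res_l = loocv(toy)
        assert res_k.auc == pytest.approx(res_l.auc, abs=1e-12)

    def test_fold_sizes_near_equal(self, small):
        seen = []

        def spy(A):
            seen.append(int(small.nnz - A.sum()))
            return np.ones_like(A)

        kfold_cv(small, folds=4, repeats=1, seed=0, score_fn=spy)
        q, r = divmod(small.nnz, 4)
        assert sorted(seen, reverse=True) == [q + 1] * r + [q] * (4 - r)
        assert sum(seen) == small.nnz

    def test_masking_restores_dataset(self, small):
        before = small.adjacency.copy()
        kfold_cv(small, folds=3, repeats=1, seed=2,
                 score_fn=lambda A: np.ones_like(A))
        np.testing.assert_array_equal(small.adjacency, before)

    def test_sd_reported_over_repeats(self, small):
        res = kfold_cv(small, folds=3, repeats=3, seed=1)
        assert len(res.auc_per_repeat) == 3
        assert res.sd_auc == pytest.approx(np.std(res.auc_per_repeat, ddof=1))

    def test_invalid_folds_rejected(self, small):
        with pytest.raises(ValueError):
            kfold_cv(small, folds=1)


def test_kfold_does_not_exceed_loocv_on_planted_data():
    """Masking a fifth of the edges per fold removes more of the profile
    signal than masking one edge, so k-fold AUC should not beat LOOCV."""
    ds = generate_synthetic(SyntheticSpec(10, 24, 2, 0.5, 0.02, seed=1))
    res_l = loocv(ds)
    res_k = kfold_cv(ds, folds=5, repeats=3, seed=1)
    assert 0.0 <= res_k.mean_auc <= res_l.auc + 0.02
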