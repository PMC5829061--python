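"""Shrinkage LDA, stacking fusion, voting, and cross-validation plumbing."""

import numpy as np
import pytest

from hbci.classify import (
    BINARY_PROBLEMS,
    majority_vote,
    meta_decision,
    meta_fit,
    slda_decision,
    slda_fit,
    stratified_folds,
)


def _clouds(n=200, d=10, sep=6.0, seed=0, cov=None):
    rng = np.random.default_rng(seed)
    cov = np.eye(d) if cov is None else cov
    L = np.linalg.cholesky(cov)
    mu = np.zeros(d)
    mu[0] = sep / 2
    Xp = rng.standard_normal((n, d)) @ L.T + mu
    Xn = rng.standard_normal((n, d)) @ L.T - mu
    X = np.vstack([Xp, Xn])
    y = np.array(["pos"] * n + ["neg"] * n)
    return X, y


class TestSLDA:
    def test_separable_clouds_high_heldout_accuracy(self):
        X, y = _clouds(seed=1)
        model = slda_fit(X, y, positive="pos")
        Xt, yt = _clouds(seed=2)
        pred = np.where(slda_decision(model, Xt) > 0, "pos", "neg")
        assert (pred == yt).mean() >= 0.99

    def test_full_shrinkage_reduces_to_nearest_mean(self):
        X, y = _clouds(n=50, seed=3)
        model = slda_fit(X, y, positive="pos", lam=1.0, literal_identity=True)
        diff = X[y == "pos"].mean(0) - X[y == "neg"].mean(0)
        cos = model.w @ diff / (np.linalg.norm(model.w) * np.linalg.norm(diff))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_columns_still_fit(self):
        """Shrinkage keeps the singular empirical covariance invertible."""
        X, y = _clouds(n=30, d=5, seed=4)
        X = np.hstack([X, X])  # exactly collinear features
        model = slda_fit(X, y, positive="pos")
        assert np.all(np.isfinite(model.w))
        assert 0 < model.lam <= 1

    def test_midpoint_decision_is_zero(self):
        X, y = _clouds(n=100, seed=5)
        model = slda_fit(X, y, positive="pos")
        mid = 0.5 * (model.mean_pos + model.mean_neg)
        assert slda_decision(model, mid[None, :])[0] == pytest.approx(0.0, abs=1e-9)

    def test_class_means_get_opposite_signs(self):
        X, y = _clouds(n=100, seed=6)
        model = slda_fit(X, y, positive="pos")
        d_pos = slda_decision(model, model.mean_pos[None, :])[0]
        d_neg = slda_decision(model, model.mean_neg[None, :])[0]
        assert d_pos > 0 > d_neg

    def test_translation_invariance_of_decisions(self):
        X, y = _clouds(n=80, seed=7)
        shift = np.full(X.shape[1], 13.7)
        m0 = slda_fit(X, y, positive="pos")
        m1 = slda_fit(X + shift, y, positive="pos")
        Xt, _ = _clouds(n=40, seed=8)
        assert np.allclose(
            slda_decision(m0, Xt), slda_decision(m1, Xt + shift), atol=1e-8
        )

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            slda_fit(X, np.array(["a"] * 10))

    def test_dimension_mismatch_rejected(self):
        X, y = _clouds(n=20, d=4, seed=9)
        model = slda_fit(X, y, positive="pos")
        with pytest.raises(ValueError, match="dimension"):
            slda_decision(model, np.zeros((2, 5)))

    def test_agrees_with_reference_shrinkage_lda(self):
        """Independent route: sklearn's Ledoit-Wolf LDA on the same data."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(10)
        d = 20
        A = rng.standard_normal((d, d))
        cov = A @ A.T / d + np.eye(d)
        X, y = _clouds(n=60, d=d, sep=2.0, seed=11, cov=cov)
        Xt, yt = _clouds(n=200, d=d, sep=2.0, seed=12, cov=cov)
        mine = np.where(slda_decision(slda_fit(X, y, positive="pos"), Xt) > 0,
                        "pos", "neg")
        ref = sklearn.LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto"
        ).fit(X, y).predict(Xt)
        assert (mine == ref).mean() >= 0.95


class TestMeta:
    @staticmethod
    def _binary_decisions(n, acc, rng, margin=1.0):
        """Decision values that are correct with probability ``acc``."""
        y = np.where(rng.random(n) < 0.5, "pos", "neg")
        sign = np.where(y == "pos", 1.0, -1.0)
        correct = rng.random(n) < acc
        d = sign * np.where(correct, 1.0, -1.0) * (margin + rng.random(n))
        return d, y

    def test_informative_plus_noise_not_degraded(self):
        rng = np.random.default_rng(0)
        d_eeg, y = self._binary_decisions(600, 0.98, rng)
        d_nirs = rng.standard_normal(600)
        fit, test = np.arange(300), np.arange(300, 600)
        meta = meta_fit(d_eeg[fit], d_nirs[fit], y[fit], positive="pos")
        pred = np.where(meta_decision(meta, d_eeg[test], d_nirs[test]) > 0,
                        "pos", "neg")
        eeg_only = np.where(d_eeg[test] > 0, "pos", "neg")
        acc_meta = (pred == y[test]).mean()
        acc_eeg = (eeg_only == y[test]).mean()
        assert acc_meta >= acc_eeg - 0.02

    def test_identical_modalities_match_base(self):
        rng = np.random.default_rng(1)
        d, y = self._binary_decisions(400, 0.8, rng)
        fit, test = np.arange(200), np.arange(200, 400)
        meta = meta_fit(d[fit], d[fit], y[fit], positive="pos")
        pred = np.where(meta_decision(meta, d[test], d[test]) > 0, "pos", "neg")
        base = np.where(d[test] > 0, "pos", "neg")
        assert (pred == base).mean() >= 0.99

    def test_complementary_modalities_fuse_above_either(self):
        """Two ~75%-accurate modalities with independent errors fuse higher."""
        rng = np.random.default_rng(2)
        n = 600
        y = np.where(rng.random(n) < 0.5, "pos", "neg")
        sign = np.where(y == "pos", 1.0, -1.0)
        d_eeg = sign + rng.standard_normal(n) * 1.5  # ~75 % alone
        d_nirs = sign + rng.standard_normal(n) * 1.5
        fit, test = np.arange(300), np.arange(300, 600)
        meta = meta_fit(d_eeg[fit], d_nirs[fit], y[fit], positive="pos")
        dm = meta_decision(meta, d_eeg[test], d_nirs[test])
        acc = lambda d: (np.where(d > 0, "pos", "neg") == y[test]).mean()
        assert acc(dm) > acc(d_eeg[test])
        assert acc(dm) > acc(d_nirs[test])

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            meta_fit(np.zeros(5), np.zeros(6), np.array(["a"] * 5))


class TestVoting:
    @pytest.mark.parametrize(
        "votes,confs,winner",
        [
            (("MA", "MA", "MI"), (0.1, 0.2, 5.0), "MA"),
            (("MA", "IS", "MI"), (0.9, 0.1, 0.2), "MA"),
            (("MI", "MI", "MI"), (1, 1, 1), "MI"),
            (("MA", "IS", "MI"), (0.1, 0.9, 0.2), "IS"),
        ],
    )
    def test_majority_and_confidence_tiebreak(self, votes, confs, winner):
        assert majority_vote(votes, confs) == winner

    def test_problem_ids_partition_class_pairs(self):
        ids = {frozenset((p.positive, p.negative)) for p in BINARY_PROBLEMS}
        assert ids == {
            frozenset(("MA", "MI")),
            frozenset(("MA", "IS")),
            frozenset(("MI", "IS")),
        }


class TestFolds:
    def test_stratified_folds_balance_classes(self):
        labels = np.array(["MA", "MI", "IS"] * 30)
        folds = stratified_folds(labels, 10, np.random.default_rng(0))
        assert len(folds) == 10
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(90))
        for f in folds:
            vals, counts = np.unique(labels[f], return_counts=True)
            assert len(vals) == 3 and np.all(counts == 3)

    def test_k_above_class_count_rejected(self):
        labels = np.array(["MA"] * 5 + ["MI"] * 5)
        with pytest.raises(ValueError, match="smallest class"):
            stratified_folds(labels, 6, np.random.default_rng(0))
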