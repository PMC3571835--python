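"""LS-SVM (vs direct dense-solve oracle), grid search contract, BPNN."""

import numpy as np
import pytest

from hyperseed.classifiers import (
    BPNNModel,
    LSSVMMulticlass,
    apply_half_band_rule,
    decision_value_lssvm,
    default_gamma_grid,
    default_sigma2_grid,
    fit_bpnn,
    fit_lssvm,
    fit_lssvm_binary,
    grid_search_lssvm,
    predict_bpnn,
    predict_lssvm,
    vote_majority,
)
from hyperseed.errors import LabelError, ParameterError


def three_class_toy(rng, n=8, sep=4.0):
    centers = [(0.0, 0.0), (sep, 0.0), (0.0, sep)]
    X = np.vstack([rng.normal(c, 0.2, (n, 2)) for c in centers])
    labels = np.array(sum(([lab] * n for lab in ("a", "b", "c")), []))
    return X, labels


class TestLssvmBinary:
    def test_separates_two_points(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([-1.0, 1.0])
        m = fit_lssvm_binary(X, y, gamma=10.0, sigma2=1.0)
        assert np.all(np.sign(decision_value_lssvm(m, X)) == y)

    def test_alpha_label_balance(self, rng):
        X = rng.random((10, 3))
        y = np.where(np.arange(10) < 5, 1.0, -1.0)
        m = fit_lssvm_binary(X, y, 4.0, 2.0)
        assert abs(np.sum(m.alpha * m.y)) < 1e-8
        assert m.residual < 1e-8

    def test_matches_direct_dense_solve_oracle(self, rng):
        # assemble the (n+1)-system independently and solve with lstsq
        for _ in range(5):
            X = rng.random((6, 2))
            y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
            gamma, sigma2 = 3.0, 1.5
            m = fit_lssvm_binary(X, y, gamma, sigma2)
            d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            K = np.exp(-d2 / sigma2)
            A = np.zeros((7, 7))
            A[0, 1:] = y
            A[1:, 0] = y
            A[1:, 1:] = np.outer(y, y) * K + np.eye(6) / gamma
            rhs = np.zeros(7)
            rhs[1:] = 1.0
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            assert abs(m.b - sol[0]) < 1e-10
            assert np.allclose(m.alpha, sol[1:], atol=1e-10)

    def test_permutation_invariant_decisions(self, rng):
        X = rng.random((12, 3))
        y = np.where(np.arange(12) % 2 == 0, 1.0, -1.0)
        perm = rng.permutation(12)
        q = rng.random((4, 3))
        a = decision_value_lssvm(fit_lssvm_binary(X, y, 5.0, 2.0), q)
        b = decision_value_lssvm(fit_lssvm_binary(X[perm], y[perm], 5.0, 2.0), q)
        assert np.allclose(a, b, atol=1e-8)

    def test_large_gamma_drives_training_error_down(self, rng):
        X, labels = three_class_toy(rng)
        y = np.where(labels == "a", 1.0, -1.0)
        errs = []
        for gamma in (0.01, 1e4):
            m = fit_lssvm_binary(X, y, gamma, 4.0)
            errs.append(np.mean(np.sign(decision_value_lssvm(m, X)) != y))
        assert errs[1] == 0.0
        assert errs[1] <= errs[0]

    def test_single_class_rejected(self, rng):
        with pytest.raises(LabelError):
            fit_lssvm_binary(rng.random((4, 2)), np.ones(4), 1.0, 1.0)

    def test_nonpositive_hyperparameters_rejected(self, rng):
        X, y = rng.random((4, 2)), np.array([1.0, 1, -1, -1])
        with pytest.raises(ParameterError):
            fit_lssvm_binary(X, y, 0.0, 1.0)
        with pytest.raises(ParameterError):
            fit_lssvm_binary(X, y, 1.0, -2.0)


class TestLssvmMulticlass:
    def test_separable_toy_fully_learned(self, rng):
        X, labels = three_class_toy(rng)
        model = fit_lssvm(X, labels, gamma=10.0, sigma2=2.0)
        assert len(model.machines) == 3  # C(3,2)
        assert np.all(predict_lssvm(model, X) == labels)

    def test_vote_tie_goes_to_first_class(self):
        # engineered 3-way cycle: each class wins exactly one pairwise duel
        signs = {
            (0, 1): np.array([1.0]),
            (1, 2): np.array([1.0]),
            (0, 2): np.array([-1.0]),
        }
        assert vote_majority(signs, 3, 1)[0] == 0

    def test_duplicate_queries_identical_predictions(self, rng):
        X, labels = three_class_toy(rng)
        model = fit_lssvm(X, labels, 10.0, 2.0)
        q = np.vstack([X[3], X[3]])
        p = predict_lssvm(model, q)
        assert p[0] == p[1]

    def test_serialization_round_trip(self, rng):
        X, labels = three_class_toy(rng, n=4)
        model = fit_lssvm(X, labels, 2.0, 4.0)
        back = LSSVMMulticlass.from_dict(model.to_dict())
        assert np.all(predict_lssvm(back, X) == predict_lssvm(model, X))


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        X, labels = three_class_toy(rng, n=4)
        res = grid_search_lssvm(X, labels, [8.0], [4.0], folds=2, seed=0)
        assert (res.best_gamma, res.best_sigma2) == (8.0, 4.0)
        assert len(res.cv_surface) == 1

    def test_default_grids_span_stated_ranges(self):
        g = default_gamma_grid()
        s = default_sigma2_grid()
        assert g[0] == 0.5 and g[-1] == 2.0**10 and len(g) == 12
        assert s[0] == 2.0 and s[-1] == 2.0**15 and len(s) == 15

    def test_best_pair_always_inside_grids(self, rng):
        X, labels = three_class_toy(rng, n=12, sep=1.5)
        res = grid_search_lssvm(X, labels, folds=3, seed=1)
        assert 2.0**-1 <= res.best_gamma <= 2.0**10
        assert 2.0 <= res.best_sigma2 <= 2.0**15
        assert res.best_gamma in default_gamma_grid()
        assert res.best_sigma2 in default_sigma2_grid()

    def test_best_attains_minimal_rmsecv(self, rng):
        X, labels = three_class_toy(rng, n=6, sep=1.0)
        res = grid_search_lssvm(X, labels, [0.5, 4.0], [2.0, 16.0], folds=3, seed=2)
        surf = res.cv_surface
        best_row = surf[
            (surf.gamma == res.best_gamma) & (surf.sigma2 == res.best_sigma2)
        ]
        assert best_row.rmsecv.iloc[0] == surf.rmsecv.min()

    def test_same_seed_identical_surface(self, rng):
        X, labels = three_class_toy(rng, n=6, sep=1.0)
        a = grid_search_lssvm(X, labels, [1.0, 2.0], [2.0, 8.0], folds=3, seed=9)
        b = grid_search_lssvm(X, labels, [1.0, 2.0], [2.0, 8.0], folds=3, seed=9)
        assert a.cv_surface.equals(b.cv_surface)
        assert (a.best_gamma, a.best_sigma2) == (b.best_gamma, b.best_sigma2)

    def test_infeasible_stratification_rejected(self, rng):
        X, labels = three_class_toy(rng, n=3)
        with pytest.raises(ParameterError):
            grid_search_lssvm(X, labels, [1.0], [2.0], folds=5, seed=0)


class TestBpnn:
    def test_xor_learnable_within_epoch_budget(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        labels = np.array(["same", "diff", "diff", "same"])
        final = []
        for seed in range(5):
            m = fit_bpnn(
                X, labels, hidden=4, learn_rate=0.5, momentum=0.9,
                max_epochs=1000, seed=seed,
            )
            final.append(m.loss_curve[-1])
        assert min(final) < 0.01

    def test_zero_rates_leave_weights_unchanged(self, rng):
        X, labels = three_class_toy(rng, n=3)
        m0 = fit_bpnn(X, labels, learn_rate=0.0, momentum=0.0, max_epochs=50, seed=3)
        ref = fit_bpnn(X, labels, learn_rate=0.0, momentum=0.0, max_epochs=1, seed=3)
        assert np.array_equal(m0.W1, ref.W1)
        assert np.array_equal(m0.W2, ref.W2)

    def test_same_seed_identical_weights(self, rng):
        X, labels = three_class_toy(rng, n=4)
        a = fit_bpnn(X, labels, max_epochs=100, seed=11)
        b = fit_bpnn(X, labels, max_epochs=100, seed=11)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)

    def test_loss_nonincreasing_with_small_rate_no_momentum(self, rng):
        X, labels = three_class_toy(rng, n=5)
        m = fit_bpnn(X, labels, learn_rate=1e-3, momentum=0.0, max_epochs=300, seed=0)
        assert np.all(np.diff(m.loss_curve) <= 1e-12)

    def test_half_band_rule_examples(self):
        classes = ["a", "b", "c"]
        outputs = np.array(
            [
                [0.7, 0.2, 0.1],  # recognized as first class
                [0.4, 0.3, 0.3],  # nothing near 1 -> unrecognized
                [0.9, 0.6, 0.0],  # second unit violates the band
            ]
        )
        labels, valid = apply_half_band_rule(outputs, classes)
        assert labels[0] == "a" and valid[0]
        assert labels[1] is None and not valid[1]
        assert labels[2] is None and not valid[2]

    def test_predict_on_separable_toy(self, rng):
        X, labels = three_class_toy(rng)
        m = fit_bpnn(X, labels, hidden=6, learn_rate=0.5, max_epochs=1000, seed=1)
        pred, valid = predict_bpnn(m, X)
        acc = np.mean([p == t for p, t in zip(pred, labels)])
        assert acc >= 0.9

    def test_serialization_round_trip(self, rng):
        X, labels = three_class_toy(rng, n=3)
        m = fit_bpnn(X, labels, max_epochs=20, seed=2)
        back = BPNNModel.from_dict(m.to_dict())
        pa, _ = predict_bpnn(m, X)
        pb, _ = predict_bpnn(back, X)
        assert np.all(pa == pb)

    def test_invalid_momentum_rejected(self, rng):
        X, labels = three_class_toy(rng, n=3)
        with pytest.raises(ParameterError):
            fit_bpnn(X, labels, momentum=1.0)
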