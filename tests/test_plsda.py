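import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from specfuse import ClassAlphabet
from specfuse.exceptions import ShapeError, SpecfuseError, StratificationError
from specfuse.plsda import (
    NodeCoding,
    assign_classes,
    choose_n_lv,
    cross_validate,
    decode_coding,
    encode_labels,
    fit_plsda,
    predict_nodes,
    simpls_fit,
)


def two_class_blobs(n_per=20, sep=4.0, p=6, seed=0):
    rng = np.random.default_rng(seed)
    alphabet = ClassAlphabet(("A", "B"))
    labels = np.array(["A"] * n_per + ["B"] * n_per, dtype=object)
    X = rng.standard_normal((2 * n_per, p))
    X[n_per:, 0] += sep
    return X, encode_labels(labels, alphabet), labels, alphabet


class TestNodeCoding:
    def test_study_classes_map_to_unit_rows(self, alphabet8):
        coding = encode_labels(np.array(["ACD", "PR"], dtype=object), alphabet8)
        expected = np.zeros((2, 8))
        expected[0, 0] = 1.0  # ACD is the first identity
        expected[1, 6] = 1.0  # PR is the seventh
        np.testing.assert_array_equal(coding.matrix, expected)
        assert (coding.matrix.sum(axis=1) == 1).all()

    def test_decode_inverts_encode(self, alphabet8, rng):
        labels = rng.choice(alphabet8.names, size=30).astype(object)
        np.testing.assert_array_equal(
            decode_coding(encode_labels(labels, alphabet8)), labels)

    def test_single_class_constant_node(self, alphabet8):
        coding = encode_labels(np.array(["HDI"] * 5, dtype=object), alphabet8)
        np.testing.assert_array_equal(coding.matrix[:, 4], np.ones(5))


class TestSimpls:
    def test_full_rank_equals_ols_oracle(self, rng):
        X = rng.standard_normal((12, 5))
        labels = np.array(list("AABBBCCAABBC"), dtype=object)
        coding = encode_labels(labels, ClassAlphabet(("A", "B", "C")))
        fit = simpls_fit(X, coding.matrix, 5)
        A = np.column_stack([np.ones(12), X])
        B, *_ = np.linalg.lstsq(A, coding.matrix, rcond=None)
        ols_pred = A @ B
        np.testing.assert_allclose(fit.predict(X), ols_pred, atol=1e-8)

    def test_single_response_matches_sklearn_nipals(self, rng):
        # SIMPLS and NIPALS coincide for a univariate response
        X = rng.standard_normal((25, 10))
        y = X @ rng.standard_normal(10) + 0.1 * rng.standard_normal(25)
        ours = simpls_fit(X, y[:, None], 3).predict(X, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y).predict(X)
        np.testing.assert_allclose(ours[:, 0], ref.ravel(), atol=1e-8)

    def test_multi_response_close_to_sklearn(self, rng):
        X = rng.standard_normal((30, 12))
        Y = X[:, :3] @ rng.standard_normal((3, 4)) \
            + 0.05 * rng.standard_normal((30, 4))
        ours = simpls_fit(X, Y, 3).predict(X, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, Y).predict(X)
        # different algorithms, same subspace family: agree loosely
        assert np.corrcoef(ours.ravel(), ref.ravel())[0, 1] > 0.999

    def test_component_bound_enforced(self, rng):
        with pytest.raises(SpecfuseError):
            simpls_fit(rng.standard_normal((5, 3)), rng.standard_normal((5, 2)), 5)

    def test_hand_built_single_component(self):
        # 1-LV model checked against explicit score x loading arithmetic
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        y = np.array([[2.0], [1.0], [-2.0], [-1.0]])
        fit = simpls_fit(X, y, 1)
        S = X.T @ y  # already centered
        r = S[:, 0]
        t = X @ r
        t_norm = np.linalg.norm(t)
        q = float(y[:, 0] @ (t / t_norm))
        expected = (X @ (r / t_norm)) * q
        np.testing.assert_allclose(fit.predict(X, 1)[:, 0], expected, atol=1e-10)


class TestPlsdaModel:
    def test_separable_blobs_fully_classified(self):
        # two well-separated Gaussian classes in 2-D, single latent variable
        X, coding, labels, alphabet = two_class_blobs(sep=6.0, p=2)
        model = fit_plsda(X, coding, 1)
        assert (model.predict_labels(X) == labels).all()

    def test_sample_order_invariance(self, rng):
        X, coding, labels, alphabet = two_class_blobs(seed=3)
        perm = rng.permutation(X.shape[0])
        m1 = fit_plsda(X, coding, 3)
        m2 = fit_plsda(X[perm], NodeCoding(alphabet, coding.matrix[perm]), 3)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-10)

    def test_training_rows_reproduce_fit_time_predictions(self):
        X, coding, *_ = two_class_blobs(seed=5)
        model = fit_plsda(X, coding, 2)
        first = predict_nodes(model, X)
        np.testing.assert_array_equal(first, predict_nodes(model, X))
        dup = predict_nodes(model, np.vstack([X[0], X[0]]))
        np.testing.assert_array_equal(dup[0], dup[1])

    def test_variable_mismatch_raises(self):
        X, coding, *_ = two_class_blobs()
        model = fit_plsda(X, coding, 2)
        with pytest.raises(ShapeError):
            predict_nodes(model, X[:, :3])

    def test_column_permutation_invariance(self, rng):
        X, coding, *_ = two_class_blobs(seed=9)
        perm = rng.permutation(X.shape[1])
        n1 = fit_plsda(X, coding, 3).predict_nodes(X)
        n2 = fit_plsda(X[:, perm], coding, 3).predict_nodes(X[:, perm])
        np.testing.assert_allclose(n1, n2, atol=1e-10)

    def test_training_accuracy_nondecreasing_in_n_lv(self, rng):
        X, coding, labels, alphabet = two_class_blobs(n_per=25, sep=1.2, seed=17)
        accs = []
        for n_lv in range(1, 6):
            model = fit_plsda(X, coding, n_lv)
            accs.append(float(np.mean(model.predict_labels(X) == labels)))
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))


class TestAssignClasses:
    def test_argmax_row(self, alphabet8):
        nodes = np.zeros((1, 8))
        nodes[0, 1] = 0.9
        nodes[0, 0] = 0.1
        assert assign_classes(nodes, alphabet8)[0] == "ACI"

    def test_tie_breaks_to_lowest_index(self, alphabet8):
        nodes = np.zeros((1, 8))
        nodes[0, 0] = nodes[0, 2] = 0.7
        assert assign_classes(nodes, alphabet8)[0] == "ACD"

    def test_matches_bruteforce_scan(self, alphabet8, rng):
        nodes = rng.normal(size=(50, 8))
        got = assign_classes(nodes, alphabet8)
        for i in range(50):
            best, best_v = 0, nodes[i, 0]
            for j in range(1, 8):
                if nodes[i, j] > best_v:
                    best, best_v = j, nodes[i, j]
            assert got[i] == alphabet8.names[best]

    def test_nonfinite_raises(self, alphabet8):
        with pytest.raises(SpecfuseError):
            assign_classes(np.array([[np.nan] * 8]), alphabet8)


class TestModelSelectionAndCv:
    def test_choose_n_lv_separable_returns_one(self):
        X, coding, *_ = two_class_blobs(n_per=20, sep=6.0)
        assert choose_n_lv(X, coding, max_lv=5, folds=4, seed=0) == 1

    def test_choose_n_lv_within_bound_and_deterministic(self, rng):
        X, coding, *_ = two_class_blobs(n_per=15, sep=0.0, seed=21)
        got = choose_n_lv(X, coding, max_lv=4, folds=5, seed=1)
        assert 1 <= got <= 4
        assert got == choose_n_lv(X, coding, max_lv=4, folds=5, seed=1)

    def test_leave_one_out_structure(self):
        X, coding, labels, alphabet = two_class_blobs(n_per=8)
        cv = cross_validate(X, coding, 1, folds=8, seed=0)
        assert cv.nodes.shape == (16, 2)
        assert not np.isnan(cv.nodes).any()
        assert (np.bincount(cv.fold_of_sample, minlength=8) > 0).all()

    def test_separable_cv_perfect(self):
        X, coding, labels, _ = two_class_blobs(n_per=20, sep=6.0)
        cv = cross_validate(X, coding, 1, folds=5, seed=0)
        assert (cv.assigned == labels).all()

    def test_same_seed_same_folds_and_nodes(self):
        X, coding, *_ = two_class_blobs(seed=2)
        a = cross_validate(X, coding, 2, folds=5, seed=3)
        b = cross_validate(X, coding, 2, folds=5, seed=3)
        np.testing.assert_array_equal(a.fold_of_sample, b.fold_of_sample)
        np.testing.assert_array_equal(a.nodes, b.nodes)

    def test_too_many_folds_raises(self):
        X, coding, *_ = two_class_blobs(n_per=3)
        with pytest.raises(StratificationError):
            cross_validate(X, coding, 1, folds=5, seed=0)
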