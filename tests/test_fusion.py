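import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfuse import ClassAlphabet
from specfuse.exceptions import AlignmentError
from specfuse.fusion import (
    UNASSIGNED,
    BlockScaler,
    bayes_fuse,
    concat_fuse,
    decide,
    fuse_dataset,
    node_matrix_to_probabilities,
    node_to_probability,
)
from specfuse.plsda import encode_labels, fit_plsda


def random_prob(rng, k=8):
    p = rng.dirichlet(np.ones(k))
    return p


class TestNodeToProbability:
    def test_worked_example(self):
        np.testing.assert_allclose(
            node_to_probability([-0.2, 0.5, 0.7]),
            [0.0, 5.0 / 12.0, 7.0 / 12.0])

    def test_one_hot_is_identity(self):
        row = np.array([0.0, 1.0, 0.0, 0.0])
        np.testing.assert_array_equal(node_to_probability(row), row)

    def test_all_negative_gives_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="nonpositive"):
            p = node_to_probability([-0.5, -0.1, -2.0])
        np.testing.assert_allclose(p, np.full(3, 1.0 / 3.0))

    def test_vectorized_matches_rowwise(self, rng):
        nodes = rng.normal(0.2, 0.5, (40, 8))
        nodes[3] = -np.abs(nodes[3])  # one degenerate row
        with pytest.warns(UserWarning):
            P = node_matrix_to_probabilities(nodes)
        for i in range(40):
            if np.all(nodes[i] <= 0):
                with pytest.warns(UserWarning):
                    expected = node_to_probability(nodes[i])
            else:
                expected = node_to_probability(nodes[i])
            np.testing.assert_allclose(P[i], expected, atol=1e-12)
        assert (P >= 0).all()
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)


class TestBayesFuse:
    def test_hand_evaluated_example(self):
        post = bayes_fuse([0.6, 0.4], [0.3, 0.7])
        np.testing.assert_allclose(post, [0.18 / 0.46, 0.28 / 0.46], atol=1e-12)

    def test_uniform_inputs_stay_uniform(self):
        u = np.full(8, 1.0 / 8.0)
        np.testing.assert_allclose(bayes_fuse(u, u), u, atol=1e-12)

    def test_certainty_dominates(self):
        pB = np.array([0.0, 1.0, 0.0])
        pC = np.array([0.3, 0.5, 0.2])
        np.testing.assert_allclose(bayes_fuse(pB, pC), pB, atol=1e-12)

    def test_commutative_normalized_uniform_identity(self, rng):
        u = np.full(8, 1.0 / 8.0)
        for _ in range(200):
            pB, pC = random_prob(rng), random_prob(rng)
            post = bayes_fuse(pB, pC)
            np.testing.assert_allclose(post, bayes_fuse(pC, pB), atol=1e-12)
            assert post.sum() == pytest.approx(1.0, abs=1e-9)
            assert (post >= 0).all()
            np.testing.assert_allclose(bayes_fuse(pB, u), pB, atol=1e-12)

    def test_monotone_in_component(self, rng):
        for _ in range(50):
            pB, pC = random_prob(rng), random_prob(rng)
            j = int(rng.integers(8))
            post = bayes_fuse(pB, pC)
            boosted = pB.copy()
            boosted[j] += 0.2
            boosted /= boosted.sum()
            post2 = bayes_fuse(boosted, pC)
            assert post2[j] >= post[j] - 1e-12

    def test_disjoint_support_falls_back_to_average(self):
        pB = np.array([1.0, 0.0, 0.0])
        pC = np.array([0.0, 0.5, 0.5])
        np.testing.assert_allclose(bayes_fuse(pB, pC),
                                   (pB + pC) / 2.0, atol=1e-12)

    def test_nonuniform_prior_weights_products(self):
        prior = np.array([0.9, 0.1])
        post = bayes_fuse([0.5, 0.5], [0.5, 0.5], prior)
        np.testing.assert_allclose(post, prior, atol=1e-12)


class TestDecide:
    def setup_method(self):
        self.alphabet = ClassAlphabet()

    def test_clear_winner(self):
        post = np.array([0.6, 0.39, 0.01, 0, 0, 0, 0, 0])
        res = decide(post, self.alphabet, 0.01)
        assert res.assigned == "ACD"
        assert res.margin == pytest.approx(0.21)

    def test_margin_equal_to_threshold_unassigned(self):
        res = decide(np.array([0.505, 0.495]), ClassAlphabet(("A", "B")), 0.01)
        assert res.assigned == UNASSIGNED
        assert res.margin == pytest.approx(0.01)

    def test_exact_tie_unassigned(self):
        post = np.full(8, 0.0)
        post[0] = post[2] = 0.5
        res = decide(post, self.alphabet, 0.01)
        assert res.assigned == UNASSIGNED
        assert res.margin == 0.0


class TestFuseDataset:
    def setup_method(self):
        self.alphabet = ClassAlphabet(("A", "B", "C", "D"))

    def test_single_confident_modality_wins(self):
        # modality B confidently correct (class A); C wrong and diffuse
        nb = np.array([[0.9, 0.05, 0.03, 0.02]])
        nc = np.array([[0.2, 0.3, 0.26, 0.24]])
        rep = fuse_dataset(nb, nc, self.alphabet)
        assert rep.assigned[0] == "A"

    def test_both_confidently_wrong_stays_wrong(self):
        # true class is A but both modalities insist on B
        nb = np.array([[0.02, 0.9, 0.05, 0.03]])
        nc = np.array([[0.03, 0.85, 0.07, 0.05]])
        rep = fuse_dataset(nb, nc, self.alphabet)
        assert rep.assigned[0] == "B"

    def test_composition_equals_per_row_ops(self, rng):
        nb = rng.normal(0.2, 0.5, (30, 4))
        nc = rng.normal(0.2, 0.5, (30, 4))
        rep = fuse_dataset(nb, nc, self.alphabet, threshold=0.01)
        import warnings
        for i in range(30):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pb = node_to_probability(nb[i])
                pc = node_to_probability(nc[i])
            expected = decide(bayes_fuse(pb, pc), self.alphabet, 0.01)
            np.testing.assert_allclose(rep.results[i].posterior,
                                       expected.posterior, atol=1e-12)
            assert rep.results[i].assigned == expected.assigned

    def test_shape_and_id_misalignment(self, rng):
        nb = rng.normal(size=(5, 4))
        with pytest.raises(AlignmentError):
            fuse_dataset(nb, rng.normal(size=(4, 4)), self.alphabet)
        with pytest.raises(AlignmentError):
            fuse_dataset(nb, nb, self.alphabet,
                         sample_ids_b=list("abcde"), sample_ids_c=list("abcdf"))


class TestConcatFuse:
    def test_fused_widths(self, rng):
        a = rng.normal(size=(4, 2593))
        b = rng.normal(size=(4, 669))
        fused, _ = concat_fuse(a, b)
        assert fused.shape == (4, 3262)
        a = rng.normal(size=(4, 83))
        b = rng.normal(size=(4, 134))
        fused, _ = concat_fuse(a, b)
        assert fused.shape == (4, 217)

    def test_row_misalignment(self, rng):
        with pytest.raises(AlignmentError):
            concat_fuse(rng.normal(size=(4, 5)), rng.normal(size=(3, 5)))

    def test_scaler_frozen_for_prediction_rows(self, rng):
        cal = [rng.normal(2, 3, (20, 6)), rng.normal(-1, 0.5, (20, 4))]
        fused_cal, scaler = concat_fuse(*cal)
        np.testing.assert_allclose(fused_cal.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(fused_cal.std(axis=0), 1.0, atol=1e-10)
        new = [rng.normal(2, 3, (5, 6)), rng.normal(-1, 0.5, (5, 4))]
        fused_new, _ = concat_fuse(*new, scaler=scaler)
        manual = np.hstack([
            (new[0] - cal[0].mean(axis=0)) / cal[0].std(axis=0),
            (new[1] - cal[1].mean(axis=0)) / cal[1].std(axis=0),
        ])
        np.testing.assert_allclose(fused_new, manual, atol=1e-10)

    def test_duplicated_block_invariance(self, rng):
        # concatenating a block with itself leaves PLS-DA assignments unchanged
        labels = np.array(["A"] * 12 + ["B"] * 12, dtype=object)
        alphabet = ClassAlphabet(("A", "B"))
        coding = encode_labels(labels, alphabet)
        X = rng.standard_normal((24, 10))
        X[12:, 0] += 1.5
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        Z, _ = concat_fuse(X, X)  # two identical autoscaled copies of Xs
        np.testing.assert_allclose(Z, np.hstack([Xs, Xs]), atol=1e-12)
        single = fit_plsda(Xs, coding, 3).predict_labels(Xs)
        doubled = fit_plsda(Z, coding, 3).predict_labels(Z)
        np.testing.assert_array_equal(doubled, single)
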