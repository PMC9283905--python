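"""Matrix-based entropy estimators: closed forms, identities, oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg as sla

from eegmetric.entropy import (
    conditional_entropy,
    entropy_gap,
    entropy_gap_from_grams,
    gaussian_gram,
    joint_entropy,
    label_gram,
    matrix_entropy,
    mutual_information,
)


def entropy_oracle(K, alpha):
    """Independent recomputation: scipy dense eigensolver, direct formula."""
    lam = sla.eigvalsh(K / np.trace(K))
    lam = lam[lam > 1e-12]
    return np.log(np.sum(lam**alpha)) / (1.0 - alpha)


class TestGaussianGram:
    def test_identical_points_give_unit_kernel(self):
        K = gaussian_gram(np.array([[1.0, 2.0], [1.0, 2.0]]), sigma=0.7)
        assert K[0, 1] == pytest.approx(1.0)

    def test_distance_sigma_sqrt2_gives_exp_minus_one(self):
        sigma = 1.3
        Y = np.array([[0.0], [sigma * np.sqrt(2.0)]])
        assert gaussian_gram(Y, sigma)[0, 1] == pytest.approx(np.exp(-1.0))

    def test_huge_bandwidth_saturates_to_ones(self, rng):
        K = gaussian_gram(rng.standard_normal((6, 3)), sigma=1e12)
        assert np.all(np.abs(K - 1.0) < 1e-6)

    def test_rejects_non_finite_points(self):
        with pytest.raises(ValueError, match="non-finite"):
            gaussian_gram(np.array([[0.0], [np.nan]]), sigma=1.0)

    def test_rejects_single_point_and_bad_sigma(self):
        with pytest.raises(ValueError):
            gaussian_gram(np.array([[1.0]]), sigma=1.0)
        with pytest.raises(ValueError, match="sigma"):
            gaussian_gram(np.zeros((3, 1)), sigma=0.0)


class TestLabelGram:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([1, 1, 2, 2], np.kron(np.eye(2), np.ones((2, 2)))),
            ([3, 3, 3], np.ones((3, 3))),
            ([1, 2, 3], np.eye(3)),
        ],
    )
    def test_block_structure(self, labels, expected):
        np.testing.assert_array_equal(label_gram(labels), expected)


class TestMatrixEntropy:
    def test_uniform_spectrum_gives_log_n(self):
        for alpha in (1.01, 2.0, 3.5):
            assert matrix_entropy(np.eye(4), alpha) == pytest.approx(
                np.log(4), abs=1e-10
            )

    def test_rank_one_gives_zero(self):
        assert matrix_entropy(np.ones((5, 5)), 2.0) == pytest.approx(0.0, abs=1e-10)

    def test_two_point_spectrum_closed_form(self):
        # normalized spectrum {0.7, 0.3} at alpha=2: S = -log(0.49 + 0.09)
        K = np.diag([0.7, 0.3])
        assert matrix_entropy(K, alpha=2.0) == pytest.approx(
            -np.log(0.7**2 + 0.3**2), abs=1e-12
        )

    def test_errors_on_bad_input(self):
        with pytest.raises(ValueError, match="trace"):
            matrix_entropy(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="negative eigenvalue"):
            matrix_entropy(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="alpha"):
            matrix_entropy(np.eye(2), alpha=0.99)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        Y = rng.standard_normal((n, 2))
        K = gaussian_gram(Y, sigma=float(rng.uniform(0.2, 3.0)))
        S = matrix_entropy(K)
        assert -1e-8 <= S <= np.log(n) + 1e-8
        p = rng.permutation(n)
        assert matrix_entropy(K[np.ix_(p, p)]) == pytest.approx(S, abs=1e-9)


class TestJointConditionalMutual:
    def test_allones_label_gram_is_hadamard_identity(self, rng):
        K_Y = gaussian_gram(rng.standard_normal((6, 2)), 1.0)
        assert joint_entropy(np.ones((6, 6)), K_Y) == pytest.approx(
            matrix_entropy(K_Y), abs=1e-12
        )

    def test_distinct_labels_identity_hadamard_gives_log_n(self, rng):
        K_Y = gaussian_gram(rng.standard_normal((5, 2)), 1.0)
        K_L = label_gram([1, 2, 3, 4, 5])
        assert joint_entropy(K_L, K_Y) == pytest.approx(np.log(5), abs=1e-10)

    def test_joint_matches_dense_eigen_oracle_on_toy_set(self):
        Y = np.array([[0.0, 0.0], [0.2, 0.1], [3.0, 3.0], [3.2, 2.9]])
        K_L = label_gram([1, 1, 2, 2])
        K_Y = gaussian_gram(Y, sigma=0.8)
        expected = entropy_oracle(K_L * K_Y, 1.01)
        assert joint_entropy(K_L, K_Y) == pytest.approx(expected, abs=1e-12)

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError, match="same shape"):
            joint_entropy(np.eye(3), np.eye(4))

    def test_single_class_conditional_entropy_is_zero(self, rng):
        K_Y = gaussian_gram(rng.standard_normal((7, 3)), 1.0)
        assert conditional_entropy(np.ones((7, 7)), K_Y) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_identical_points_conditional_equals_label_entropy(self):
        K_L = label_gram([1, 1, 2, 2, 2])
        K_Y = np.ones((5, 5))
        assert conditional_entropy(K_L, K_Y) == pytest.approx(
            matrix_entropy(K_L), abs=1e-10
        )

    def test_separated_clusters_have_small_conditional_entropy(self, clusters8):
        X, y = clusters8
        K_L = label_gram(y)
        K_Y = gaussian_gram(X, sigma=0.5)
        assert conditional_entropy(K_L, K_Y) < 0.05 * matrix_entropy(K_L)

    def test_mutual_information_vanishes_for_degenerate_marginals(self, rng):
        K_Y = gaussian_gram(rng.standard_normal((6, 2)), 1.0)
        K_L = label_gram([1, 1, 1, 2, 2, 2])
        assert mutual_information(K_L, np.ones((6, 6))) == pytest.approx(0, abs=1e-8)
        assert mutual_information(np.ones((6, 6)), K_Y) == pytest.approx(0, abs=1e-8)

    def test_chain_rule_identity(self, clusters8):
        X, y = clusters8
        K_L, K_Y = label_gram(y), gaussian_gram(X, sigma=0.5)
        mi = mutual_information(K_L, K_Y)
        assert mi == pytest.approx(
            matrix_entropy(K_L) - conditional_entropy(K_L, K_Y), abs=1e-10
        )

    def test_randomized_inequalities_and_oracle_agreement(self):
        # 100 seeded draws: joint dominates both marginals; values match an
        # independent scipy eigensolver recomputation to 1e-9
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 15))
            Y = rng.standard_normal((n, int(rng.integers(1, 4))))
            labels = rng.integers(1, 3, n)
            K_Y = gaussian_gram(Y, float(rng.uniform(0.3, 2.0)))
            K_L = label_gram(labels)
            J = joint_entropy(K_L, K_Y)
            assert J >= matrix_entropy(K_Y) - 1e-8
            assert J >= matrix_entropy(K_L) - 1e-8
            assert J == pytest.approx(entropy_oracle(K_L * K_Y, 1.01), abs=1e-9)
            assert matrix_entropy(K_Y) == pytest.approx(
                entropy_oracle(K_Y, 1.01), abs=1e-9
            )


class TestEntropyGap:
    def test_zero_projection_gives_exact_zero(self):
        K_L = label_gram([1, 2, 1, 2])
        Y = np.zeros((4, 2))
        assert entropy_gap(K_L, Y, sigma=1.0, n_perm=7, rng=3) == 0.0

    def test_single_class_gives_zero(self, rng):
        Y = rng.standard_normal((6, 2))
        assert entropy_gap(np.ones((6, 6)), Y, sigma=1.0, n_perm=5, rng=0) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_seeded_determinism(self, rng):
        Y = rng.standard_normal((8, 2))
        K_L = label_gram([1, 1, 1, 1, 2, 2, 2, 2])
        a = entropy_gap(K_L, Y, 1.0, n_perm=6, rng=42)
        b = entropy_gap(K_L, Y, 1.0, n_perm=6, rng=42)
        assert a == b

    def test_matches_exhaustive_permutation_oracle(self):
        # n=4: the exact expectation enumerates all 24 permutations
        Y = np.array([0.0, 0.0, 10.0, 10.0])
        K_L = label_gram([1, 1, 2, 2])
        K_Y = gaussian_gram(Y, 1.0)
        # independent brute-force enumeration via the scipy oracle
        joints = []
        for p in itertools.permutations(range(4)):
            p = np.array(p)
            joints.append(entropy_oracle(K_L * K_Y[np.ix_(p, p)], 1.01))
        exact = np.mean(joints) - entropy_oracle(K_L * K_Y, 1.01)
        assert exact > 0
        perms = [np.array(p) for p in itertools.permutations(range(4))]
        assert entropy_gap_from_grams(K_L, K_Y, perms) == pytest.approx(
            exact, abs=1e-10
        )
        # the sampled estimator converges to the enumeration
        sampled = entropy_gap(K_L, Y, sigma=1.0, n_perm=300, rng=0)
        assert sampled == pytest.approx(exact, abs=0.05)

    def test_rejects_bad_permutation_count(self):
        with pytest.raises(ValueError, match="n_perm"):
            entropy_gap(np.eye(4), np.zeros((4, 1)), 1.0, n_perm=0)

    def test_gap_closes_at_scale_extremes(self, informative_2d):
        X, y = informative_2d
        K_L = label_gram(y[:60])
        Y = X[:60, :1]
        scales = np.logspace(-4, 4, 9)
        gaps = [entropy_gap(K_L, s * Y, sigma=1.0, n_perm=10, rng=0) for s in scales]
        peak = max(gaps)
        assert peak > 0
        assert gaps[0] <= 0.1 * peak
        assert gaps[-1] <= 0.1 * peak
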