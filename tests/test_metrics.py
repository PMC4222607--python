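"""Sign metrics, mutant scans, interaction strength and conservation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from threshnet import (InteractionStrengthMatrix, Population, conservation,
                       hamming_normalized, indirect_autoregulation_r,
                       interaction_strength, population_stability,
                       sign_autoregulation_p, sign_offdiag_q,
                       single_mutant_scan, stable_networks)
from threshnet.metrics import scan_networks
from threshnet.netgen import random_network, random_networks, random_state

from oracles import mutant_scan_bruteforce, r_bruteforce


class TestHamming:
    def test_identical_states(self):
        assert hamming_normalized([1, -1, 1], [1, -1, 1]) == 0.0

    def test_opposite_states(self):
        assert hamming_normalized([1, 1], [-1, -1]) == 1.0

    def test_partial_difference(self):
        a = np.ones(10, dtype=int)
        b = a.copy()
        b[:3] = -1
        assert hamming_normalized(a, b) == 0.3

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hamming_normalized([1, 1], [1, 1, -1])


class TestSignMetrics:
    def test_p_counts_positive_diagonal(self):
        W = -np.ones((10, 10), dtype=int)
        np.fill_diagonal(W, [1] * 7 + [-1] * 3)
        assert sign_autoregulation_p(W) == 0.7
        assert sign_autoregulation_p(np.ones((4, 4), dtype=int)) == 1.0

    def test_q_counts_positive_offdiagonal(self):
        assert sign_offdiag_q(np.ones((5, 5), dtype=int)) == 1.0

    def test_sparse_denominators_use_nonzero_counts(self):
        W = np.zeros((4, 4), dtype=int)
        W[0, 0] = 1
        W[1, 1] = -1
        W[0, 1] = W[1, 0] = -1
        assert sign_autoregulation_p(W) == 0.5
        assert sign_offdiag_q(W) == 0.0

    def test_all_zero_diagonal_raises(self):
        W = np.zeros((3, 3), dtype=int)
        W[0, 1] = 1
        with pytest.raises(ValueError):
            sign_autoregulation_p(W)

    def test_r_is_one_for_uniform_sign_matrices(self):
        # products of two like signs are positive either way
        assert indirect_autoregulation_r(np.ones((5, 5), dtype=int)) == 1.0
        assert indirect_autoregulation_r(-np.ones((5, 5), dtype=int)) == 1.0

    @given(st.integers(2, 8), st.integers(0, 10 ** 9))
    def test_r_matches_bruteforce_dot_products(self, n, seed):
        W = random_network(n, np.random.default_rng(seed))
        assert indirect_autoregulation_r(W) == r_bruteforce(W)

    @given(st.integers(2, 8), st.integers(0, 10 ** 9))
    def test_p_q_invariant_under_relabelling(self, n, seed):
        """Simultaneous row/column permutation preserves p and q."""
        rng = np.random.default_rng(seed)
        W = random_network(n, rng)
        perm = rng.permutation(n)
        Wp = W[np.ix_(perm, perm)]
        assert sign_autoregulation_p(Wp) == sign_autoregulation_p(W)
        assert sign_offdiag_q(Wp) == sign_offdiag_q(W)


class TestPopulationStability:
    def test_all_stable(self, rng):
        W = np.ones((20, 10, 10), dtype=np.int8)
        S = np.stack([random_state(10, rng) for _ in range(20)])
        assert population_stability(Population(W, S)) == 1.0

    def test_none_stable(self):
        W = np.full((5, 1, 1), -1, dtype=np.int8)
        S = np.ones((5, 1), dtype=np.int8)
        assert population_stability(Population(W, S)) == 0.0


class TestSingleMutantScan:
    def test_single_gene_self_activator(self):
        """The only mutant of [[+1]] oscillates: zero viability."""
        res = single_mutant_scan(np.array([[1]]), [1])
        assert res.n_total == 1 and res.n_fixed == 0
        assert res.viability == 0.0
        assert res.robustness is None  # undefined, not zero

    def test_requires_stable_original(self):
        with pytest.raises(ValueError):
            single_mutant_scan(np.array([[-1]]), [1])

    def test_tally_bounds(self, rng):
        W, S = stable_networks(6, 5, rng)
        for w, s in zip(W, S):
            res = single_mutant_scan(w, s)
            assert 0 <= res.n_same <= res.n_fixed <= res.n_total == 36
            assert res.per_element_fixed.sum() == res.n_fixed

    @given(st.integers(0, 10 ** 9))
    def test_matches_bruteforce_enumeration_n4(self, seed):
        rng = np.random.default_rng(seed)
        W, S = stable_networks(4, 1, rng)
        res = single_mutant_scan(W[0], S[0])
        assert (res.n_total, res.n_fixed, res.n_same) == \
            mutant_scan_bruteforce(W[0], S[0])

    def test_batch_scan_matches_single(self, rng):
        W, S = stable_networks(8, 20, rng)
        batch = scan_networks(W, S)
        for k in range(20):
            res = single_mutant_scan(W[k], S[k])
            assert batch["n_fixed"][k] == res.n_fixed
            assert batch["n_same"][k] == res.n_same
            assert batch["viability"][k] == res.viability


class TestInteractionStrength:
    def test_identical_networks_give_ones(self):
        W = np.ones((7, 4, 4), dtype=np.int8)
        assert (interaction_strength(W).o == 1.0).all()

    def test_random_networks_near_half(self, rng):
        W = random_networks(10, 20_000, rng)
        o = interaction_strength(W).o
        assert np.abs(o - 0.5).max() < 0.02


class TestConservation:
    def test_frozen_signs_fully_conserved(self):
        o = InteractionStrengthMatrix(np.ones((3, 3)), t=1)
        o2 = InteractionStrengthMatrix(np.ones((3, 3)), t=2)
        assert (conservation(o, o2) == 1.0).all()

    def test_independence_baseline(self):
        o1 = InteractionStrengthMatrix(np.full((2, 2), 0.5), t=0)
        o2 = InteractionStrengthMatrix(np.full((2, 2), 0.5), t=9)
        assert (conservation(o1, o2) == 0.5).all()

    def test_biased_signs(self):
        o1 = InteractionStrengthMatrix(np.full((2, 2), 0.9), t=0)
        o2 = InteractionStrengthMatrix(np.full((2, 2), 0.9), t=1)
        # 0.9 * 0.9 + 0.1 * 0.1
        assert np.allclose(conservation(o1, o2), 0.82)

    def test_time_order_enforced(self):
        o1 = InteractionStrengthMatrix(np.full((2, 2), 0.5), t=5)
        o2 = InteractionStrengthMatrix(np.full((2, 2), 0.5), t=1)
        with pytest.raises(ValueError):
            conservation(o1, o2)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            conservation(InteractionStrengthMatrix(np.ones((2, 2))),
                         InteractionStrengthMatrix(np.ones((3, 3))))
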