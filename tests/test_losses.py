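"""Contrastive losses versus independent brute-force oracles.

The oracles below form the full similarity matrix and evaluate every term of
the weighted-softmax definitions literally, term by term, with no code shared
with the package implementation.
"""

import numpy as np
import pytest
from scipy import stats

from dnaclr.autodiff import Adam, Tensor, free_graph
from dnaclr.exceptions import BatchSizeError, InputError
from dnaclr.losses import (cosine_sim, imix_batch_loss, mimix_anchor_loss,
                           mimix_batch_loss, mimix_negative_weights,
                           mix_hidden, mix_labels, mixed_label_matrix,
                           simclr_negative_weights,
                           weighted_simclr_anchor_loss,
                           weighted_simclr_batch_loss)
from dnaclr.train import draw_mixup

TAU = 0.05


from _oracles import oracle_mimix, oracle_nt_xent, oracle_weighted_simclr

# ---------------------------------------------------------------------------


class TestCosine:
    def test_self_similarity(self):
        u = np.array([3.0, 4.0])
        assert cosine_sim(u, u) == pytest.approx(1.0)
        assert cosine_sim(u, -u) == pytest.approx(-1.0)
        assert cosine_sim([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(InputError):
            cosine_sim([0.0, 0.0], [1.0, 0.0])


class TestWeightedSimclr:
    @pytest.mark.parametrize("b", [2, 3, 4])
    def test_matches_oracle(self, b):
        rng = np.random.default_rng(b)
        za, zp = rng.normal(size=(2, b, 6))
        mine = weighted_simclr_batch_loss(za, zp, TAU).item()
        assert mine == pytest.approx(np.mean(oracle_weighted_simclr(za, zp, TAU)),
                                     abs=1e-6)

    def test_anchor_losses_match_oracle(self):
        rng = np.random.default_rng(9)
        za, zp = rng.normal(size=(2, 3, 4))
        oracle = oracle_weighted_simclr(za, zp, TAU)
        for i in range(6):
            assert weighted_simclr_anchor_loss(i, za, zp, TAU) == \
                pytest.approx(oracle[i], abs=1e-6)

    def test_identical_embeddings_give_log_2b_minus_1(self):
        b = 4
        z = np.tile(np.random.default_rng(0).normal(size=5), (b, 1))
        loss = weighted_simclr_batch_loss(z, z.copy(), TAU).item()
        assert loss == pytest.approx(np.log(2 * b - 1), abs=1e-9)

    def test_sharper_temperature_reduces_separable_loss(self):
        # positive nearly aligned, negatives orthogonal
        za = np.eye(3)[None].repeat(1, 0).reshape(3, 3)
        zp = za + 0.01
        assert weighted_simclr_batch_loss(za, zp, 0.01).item() < \
            weighted_simclr_batch_loss(za, zp, 0.05).item()

    def test_pair_permutation_invariance(self):
        rng = np.random.default_rng(2)
        za, zp = rng.normal(size=(2, 5, 8))
        perm = rng.permutation(5)
        a = weighted_simclr_batch_loss(za, zp, TAU).item()
        b = weighted_simclr_batch_loss(za[perm], zp[perm], TAU).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_batch_too_small(self):
        z = np.ones((1, 4))
        with pytest.raises(BatchSizeError):
            weighted_simclr_batch_loss(z, z, TAU)

    def test_monotone_in_positive_similarity(self):
        rng = np.random.default_rng(3)
        za, zp = rng.normal(size=(2, 4, 6))
        base = weighted_simclr_batch_loss(za, zp, TAU).item()
        zp_closer = zp + 0.5 * (za - zp)  # move positives toward anchors
        closer = weighted_simclr_batch_loss(za, zp_closer, TAU).item()
        assert np.isfinite(base) and closer < base

    def test_gradient_step_decreases_loss(self):
        rng = np.random.default_rng(4)
        za = Tensor(rng.normal(size=(2, 5)), requires_grad=True)
        zp = Tensor(rng.normal(size=(2, 5)), requires_grad=True)
        loss0 = weighted_simclr_batch_loss(za, zp, TAU)
        loss0.backward()
        step = 1e-3
        za2 = Tensor(za.data - step * za.grad)
        zp2 = Tensor(zp.data - step * zp.grad)
        assert weighted_simclr_batch_loss(za2, zp2, TAU).item() < loss0.item()


class TestNegativeWeights:
    def test_uniform_limit(self):
        # equal similarities -> every negative weight is exactly 1
        z = np.vstack([np.eye(4), np.eye(4)])  # careful: build 2B=8 rows
        w = simclr_negative_weights(0, z, TAU)
        negs = [j for j in range(8) if j not in (0, 4)]
        # cosines among distinct one-hot vectors are all 0
        np.testing.assert_allclose(w[negs], 1.0, atol=1e-12)

    def test_mean_of_negative_weights_is_one(self):
        rng = np.random.default_rng(0)
        for t in range(200):
            b = int(rng.integers(2, 6))
            z = rng.normal(size=(2 * b, 5))
            i = int(rng.integers(2 * b))
            w = simclr_negative_weights(i, z, TAU)
            negs = [j for j in range(2 * b) if j not in (i, (i + b) % (2 * b))]
            assert np.mean(w[negs]) == pytest.approx(1.0, abs=1e-9)
            assert w[(i + b) % (2 * b)] == 1.0
            assert np.all(w[negs] > 0)

    def test_two_negative_hand_computation(self):
        # B=2 in 2D: anchor x0=(1,0); others at known angles
        za = np.array([[1.0, 0.0], [0.0, 1.0]])
        zp = np.array([[1.0, 1.0], [-1.0, 0.0]])
        w = simclr_negative_weights(0, np.vstack([za, zp]), TAU)
        s = np.array([np.nan, 0.0, np.nan, -1.0])  # cos(x0, negatives 1 and 3)
        e = np.exp(s[[1, 3]] / TAU)
        expected = e / e.mean()
        assert w[1] == pytest.approx(expected[0], abs=1e-9)
        assert w[3] == pytest.approx(expected[1], abs=1e-9)


class TestMixing:
    def test_mix_hidden_endpoints(self):
        rng = np.random.default_rng(0)
        g1, g2 = rng.normal(size=(2, 3, 4, 5))
        np.testing.assert_array_equal(mix_hidden(g1, g2, 1.0).data, g1)
        np.testing.assert_array_equal(mix_hidden(g1, g2, 0.0).data, g2)
        np.testing.assert_allclose(mix_hidden(g1, g2, 0.5).data,
                                   (g1 + g2) / 2, atol=1e-12)

    def test_mix_hidden_shape_mismatch(self):
        with pytest.raises(InputError):
            mix_hidden(np.zeros((2, 3)), np.zeros((3, 2)), 0.5)

    def test_mix_labels_definition(self):
        v1, v2 = np.eye(4)[0], np.eye(4)[2]
        out = mix_labels(v1, v2, 0.3)
        assert out[0] == pytest.approx(0.3)
        assert out[2] == pytest.approx(0.7)
        assert out.sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(mix_labels(v1, v2, 1.0), v1)
        np.testing.assert_array_equal(mix_labels(v1, v1, 0.42), v1)

    def test_mix_labels_requires_one_hot(self):
        with pytest.raises(InputError):
            mix_labels(np.array([0.5, 0.5]), np.array([1.0, 0.0]), 0.5)

    def test_mixed_label_matrix_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        lam = rng.random(6)
        vm = mixed_label_matrix(lam, rng.permutation(6))
        np.testing.assert_allclose(vm.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((vm >= 0) & (vm <= 1))
        assert np.all((vm > 0).sum(axis=1) <= 2)


class TestMiMix:
    @pytest.mark.parametrize("b", [2, 3, 4])
    def test_matches_oracle(self, b):
        rng = np.random.default_rng(10 + b)
        zm, zp = rng.normal(size=(2, b, 7))
        lam = rng.random(b)
        perm = rng.permutation(b)
        vmix = mixed_label_matrix(lam, perm)
        mine = mimix_batch_loss(zm, zp, vmix, TAU).item()
        assert mine == pytest.approx(oracle_mimix(zm, zp, lam, perm, TAU),
                                     abs=1e-6)

    def test_lambda_one_reduces_to_one_directional_simclr(self):
        # with λ=1 the mixed anchor is x_i itself and the label is one-hot,
        # so the loss is the one-directional weighted softmax over {x+}
        rng = np.random.default_rng(5)
        b = 4
        zm, zp = rng.normal(size=(2, b, 6))
        vmix = mixed_label_matrix(np.ones(b), rng.permutation(b))
        mine = mimix_batch_loss(zm, zp, vmix, TAU).item()
        assert mine == pytest.approx(
            oracle_mimix(zm, zp, np.ones(b), np.arange(b), TAU), abs=1e-6)

    def test_identity_permutation_any_lambda(self):
        rng = np.random.default_rng(6)
        b = 3
        zm, zp = rng.normal(size=(2, b, 5))
        lam = rng.random(b)
        v_id = mixed_label_matrix(lam, np.arange(b))
        v_one = mixed_label_matrix(np.ones(b), np.arange(b))
        assert mimix_batch_loss(zm, zp, v_id, TAU).item() == pytest.approx(
            mimix_batch_loss(zm, zp, v_one, TAU).item(), abs=1e-9)

    def test_mean_of_per_anchor_losses(self):
        rng = np.random.default_rng(7)
        b = 4
        zm, zp = rng.normal(size=(2, b, 5))
        vmix = mixed_label_matrix(rng.random(b), rng.permutation(b))
        batch = mimix_batch_loss(zm, zp, vmix, TAU).item()
        per = [mimix_anchor_loss(i, zm, zp, vmix, TAU) for i in range(b)]
        assert batch == pytest.approx(np.mean(per), abs=1e-9)

    def test_negative_weight_normalization(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            b = int(rng.integers(2, 6))
            zm, zp = rng.normal(size=(2, b, 4))
            i = int(rng.integers(b))
            w = mimix_negative_weights(i, zm, zp, TAU)
            negs = [j for j in range(b) if j != i]
            assert np.mean(w[negs]) == pytest.approx(1.0, abs=1e-9)
            assert w[i] == 1.0

    def test_imix_identical_to_mimix(self):
        rng = np.random.default_rng(9)
        b = 3
        zm, zp = rng.normal(size=(2, b, 5))
        vmix = mixed_label_matrix(rng.random(b), rng.permutation(b))
        assert imix_batch_loss(zm, zp, vmix, TAU).item() == \
            mimix_batch_loss(zm, zp, vmix, TAU).item()


class TestAlphaOneIsNtXent:
    def test_uniform_weights_recover_nt_xent(self):
        # on embeddings where all pairwise similarities are equal the weights
        # are all 1 and the weighted loss equals NT-Xent exactly; verify the
        # general reduction numerically by scaling similarities to equality
        z = np.vstack([np.eye(4)])
        za, zp = z[:2], z[2:]
        assert weighted_simclr_batch_loss(za, zp, TAU).item() == \
            pytest.approx(oracle_nt_xent(za, zp, TAU), abs=1e-9)


class TestBetaDraws:
    def test_beta_1_1_is_uniform(self):
        rng = np.random.default_rng(0)
        draw = draw_mixup(10_000, 1.0, [0], rng)
        stat, pval = stats.kstest(draw.lambdas, "uniform")
        assert pval > 0.01
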