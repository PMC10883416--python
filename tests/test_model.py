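"""Bipartite attention auto-encoder: attention, encode/decode, loss, training.

The vectorized implementation is checked against explicit per-node,
per-neighbor loop oracles of the attention softmax, the aggregation and
the residual update, and the analytic gradients against central finite
differences.
"""

import numpy as np
import pytest

from bigatae.alignment import BipartiteGraph
from bigatae.io import SliceData
from bigatae.model import (
    BigataeParams,
    _forward_backward,
    decode,
    decoder_attention,
    encode,
    encoder_attention,
    mse_loss,
    train_bigatae,
)
from conftest import full_bipartite_graph, random_bipartite_instance


def loop_attention(E_u, E_v, graph, a_vec, slope=0.2):
    """Explicit per-node, per-neighbor evaluation of the attention softmax."""
    n_u, d = E_u.shape
    alpha = np.zeros((n_u, graph.n_v))
    for i in range(n_u):
        nbrs = sorted(j for (u, j) in graph.edges if u == i)
        if not nbrs:
            continue
        scores = []
        for j in nbrs:
            cat = np.concatenate([E_u[i], E_v[j]])
            s = float(a_vec @ cat)
            scores.append(s if s > 0 else slope * s)
        scores = np.array(scores)
        e = np.exp(scores - scores.max())
        for j, w in zip(nbrs, e / e.sum()):
            alpha[i, j] = w
    return alpha


def loop_encode(E_u, E_v, graph, a_vec, slope=0.2):
    alpha = loop_attention(E_u, E_v, graph, a_vec, slope)
    z = np.empty_like(E_u)
    for i in range(E_u.shape[0]):
        agg = np.zeros(E_u.shape[1])
        for j in range(graph.n_v):
            agg += alpha[i, j] * E_v[j]
        z[i] = E_u[i] + np.maximum(agg, 0.0)
    return z


def loop_decode(z, E_v, graph, a_vec, slope=0.2):
    abar = loop_attention(z, E_v, graph, a_vec, slope)
    out = np.empty_like(z)
    for i in range(z.shape[0]):
        agg = np.zeros(z.shape[1])
        for j in range(graph.n_v):
            agg += abar[i, j] * E_v[j]
        out[i] = z[i] - np.maximum(agg, 0.0)
    return out


class TestEncoderAttention:
    def test_single_neighbor_coefficient_is_one(self):
        rng = np.random.default_rng(0)
        E_u, E_v = rng.random((3, 4)), rng.random((5, 4))
        g = BipartiteGraph(3, 5, frozenset({(0, 2)}))
        alpha = encoder_attention(E_u, E_v, g, rng.normal(size=8))
        assert alpha[0, 2] == 1.0
        assert alpha.sum() == 1.0

    def test_zero_attention_vector_gives_uniform_coefficients(self):
        rng = np.random.default_rng(1)
        E_u, E_v = rng.random((2, 3)), rng.random((4, 3))
        g = BipartiteGraph(2, 4, frozenset({(0, 0), (0, 1), (0, 3)}))
        alpha = encoder_attention(E_u, E_v, g, np.zeros(6))
        np.testing.assert_allclose(alpha[0, [0, 1, 3]], 1 / 3)
        assert alpha[0, 2] == 0.0

    def test_matches_loop_oracle_full_graph(self):
        rng = np.random.default_rng(2)
        E_u, E_v = rng.random((4, 3)), rng.random((5, 3))
        a = rng.normal(size=6)
        g = full_bipartite_graph(4, 5)
        np.testing.assert_allclose(
            encoder_attention(E_u, E_v, g, a), loop_attention(E_u, E_v, g, a), atol=1e-6
        )

    def test_rows_sum_to_one_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            E_u, E_v, g = random_bipartite_instance(rng, 10, 12, 4)
            alpha = encoder_attention(E_u, E_v, g, rng.normal(size=8))
            deg = g.adjacency_mask().sum(axis=1)
            sums = alpha.sum(axis=1)
            np.testing.assert_allclose(sums[deg > 0], 1.0, atol=1e-6)
            np.testing.assert_array_equal(sums[deg == 0], 0.0)

    def test_nan_input_rejected(self):
        E_u = np.ones((2, 2))
        E_u[0, 0] = np.nan
        g = full_bipartite_graph(2, 2)
        with pytest.raises(ValueError, match="NaN"):
            encoder_attention(E_u, np.ones((2, 2)), g, np.zeros(4))


class TestEncodeDecode:
    def test_zero_adjacent_slice_is_identity(self):
        rng = np.random.default_rng(4)
        E_u = rng.random((4, 3))
        E_v = np.zeros((5, 3))
        g = full_bipartite_graph(4, 5)
        a = rng.normal(size=6)
        z = encode(E_u, E_v, g, a)
        np.testing.assert_array_equal(z, E_u)
        np.testing.assert_array_equal(decode(z, E_v, g, a), z)

    def test_single_nonnegative_neighbor_adds_then_subtracts_exactly(self):
        rng = np.random.default_rng(5)
        E_u = rng.random((2, 3))
        e = rng.random(3)
        E_v = np.vstack([e, rng.random(3)])
        g = BipartiteGraph(2, 2, frozenset({(0, 0)}))
        a = rng.normal(size=6)
        z = encode(E_u, E_v, g, a)
        np.testing.assert_allclose(z[0], E_u[0] + e, atol=1e-12)
        np.testing.assert_array_equal(z[1], E_u[1])
        out = decode(z, E_v, g, a)
        np.testing.assert_allclose(out[0], z[0] - e, atol=1e-12)

    def test_matches_loop_oracles_on_random_instance(self):
        rng = np.random.default_rng(6)
        E_u, E_v, g = random_bipartite_instance(rng, 7, 9, 5)
        a_enc, a_dec = rng.normal(size=10), rng.normal(size=10)
        z = encode(E_u, E_v, g, a_enc)
        np.testing.assert_allclose(z, loop_encode(E_u, E_v, g, a_enc), atol=1e-6)
        np.testing.assert_allclose(
            decode(z, E_v, g, a_dec), loop_decode(z, E_v, g, a_dec), atol=1e-6
        )

    def test_enhancement_is_entrywise_nonnegative(self):
        rng = np.random.default_rng(7)
        E_u, E_v, g = random_bipartite_instance(rng, 6, 8, 4)
        z = encode(E_u, E_v, g, rng.normal(size=8))
        assert (z - E_u >= 0).all()


class TestMseLoss:
    def test_perfect_reconstruction_is_zero(self):
        X = np.random.default_rng(8).random((3, 4))
        assert mse_loss(X, X) == 0.0

    def test_single_entry(self):
        assert mse_loss([[2.0]], [[0.0]]) == 4.0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(9)
        A, B = rng.random((7, 5)), rng.random((7, 5))
        ref = sum((A[i, j] - B[i, j]) ** 2 for i in range(7) for j in range(5)) / 35
        assert abs(mse_loss(A, B) - ref) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mse_loss(np.ones((2, 2)), np.ones((3, 2)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(10)
        E_u, E_v, g = random_bipartite_instance(rng, 5, 6, 4)
        mask = g.adjacency_mask()
        a_enc, a_dec = rng.normal(size=8), rng.normal(size=8)
        _, ge, gd, _, _ = _forward_backward(E_u, E_v, mask, a_enc, a_dec, 0.2)

        def f(ae, adx):
            return _forward_backward(E_u, E_v, mask, ae, adx, 0.2)[0]

        eps = 1e-6
        for k in range(8):
            dv = eps * np.eye(8)[k]
            num = (f(a_enc + dv, a_dec) - f(a_enc - dv, a_dec)) / (2 * eps)
            assert abs(ge[k] - num) < 1e-6
            num = (f(a_enc, a_dec + dv) - f(a_enc, a_dec - dv)) / (2 * eps)
            assert abs(gd[k] - num) < 1e-6


def _as_slices(E_u, E_v):
    def mk(X, p):
        n, d = X.shape
        return SliceData(X, np.zeros((n, 2)), [f"g{i}" for i in range(d)],
                         [f"{p}{i}" for i in range(n)])

    return mk(E_u, "u"), mk(E_v, "v")


class TestTraining:
    def test_empty_graph_returns_identity_with_warning(self):
        rng = np.random.default_rng(11)
        t, a = _as_slices(rng.random((4, 3)), rng.random((5, 3)))
        g = BipartiteGraph(4, 5, frozenset())
        with pytest.warns(UserWarning, match="empty bipartite graph"):
            enh = train_bigatae(t, a, g, BigataeParams(epochs=10))
        np.testing.assert_array_equal(enh.z, t.expression)
        assert enh.loss_history == [0.0]

    def test_training_reduces_loss(self, preprocessed_pair):
        from bigatae.alignment import binarize_alignment, sinkhorn_alignment

        t, a = preprocessed_pair
        plan = sinkhorn_alignment(t, a)
        g = binarize_alignment(plan, top_k=5)
        enh = train_bigatae(t, a, g, BigataeParams(epochs=150, seed=0))
        assert enh.loss_history[-1] < enh.loss_history[0]
        assert enh.z.shape == t.expression.shape
        assert enh.reconstruction.shape == t.expression.shape

    def test_same_seed_gives_identical_histories(self):
        rng = np.random.default_rng(12)
        E_u, E_v, g = random_bipartite_instance(rng, 8, 9, 5)
        t, a = _as_slices(E_u, E_v)
        h1 = train_bigatae(t, a, g, BigataeParams(epochs=50, seed=3)).loss_history
        h2 = train_bigatae(t, a, g, BigataeParams(epochs=50, seed=3)).loss_history
        np.testing.assert_allclose(h1, h2, atol=1e-10)

    def test_attention_vector_length_validated(self):
        rng = np.random.default_rng(13)
        E_u, E_v, g = random_bipartite_instance(rng, 4, 4, 3)
        t, a = _as_slices(E_u, E_v)
        with pytest.raises(ValueError, match="length"):
            train_bigatae(t, a, g, BigataeParams(a_enc=np.zeros(4), epochs=5))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="leaky_slope"):
            BigataeParams(leaky_slope=1.5)
        with pytest.raises(ValueError, match="epochs"):
            BigataeParams(epochs=0)
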