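"""Forward-computation contracts: normalization, convolution, GRU evolution,
pair scoring and the weighted cross-entropy loss."""

import numpy as np
import pytest

from cegcn import autodiff as ad
from cegcn import model as md
from cegcn.features import build_vocabulary, one_hot_encode, snapshot_scores
from conftest import random_adjacency, sequence_from_adjacencies


def scalar_gru_oracle(summary, prev, uz, cz, bz, ur, cr, br, uw, cw, bw):
    """Plain scalar-loop re-implementation of the matrix GRU equations."""
    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    k, m = prev.shape
    lin_z = uz @ summary + cz @ prev + bz
    lin_r = ur @ summary + cr @ prev + br
    z = np.empty((k, m))
    r = np.empty((k, m))
    for a in range(k):
        for b in range(m):
            z[a, b] = sig(lin_z[a, b])
            r[a, b] = sig(lin_r[a, b])
    cand = np.tanh(uw @ summary + cw @ (r * prev) + bw)
    out = np.empty((k, m))
    for a in range(k):
        for b in range(m):
            out[a, b] = (1 - z[a, b]) * prev[a, b] + z[a, b] * cand[a, b]
    return out, z, r, cand


def make_gru_params(rng, d, layer=0, bz_value=None):
    params = {}
    for gate in ("Z", "R", "W"):
        params[f"gru{layer}_U{gate}"] = ad.constant(rng.normal(size=(d, d)))
        params[f"gru{layer}_C{gate}"] = ad.constant(rng.normal(size=(d, d)))
        params[f"gru{layer}_B{gate}"] = ad.constant(np.zeros((d, 1)))
    if bz_value is not None:
        params[f"gru{layer}_BZ"] = ad.constant(np.full((d, 1), bz_value))
    return params


class TestNormalizeAdjacency:
    def test_empty_graph_is_identity(self):
        np.testing.assert_allclose(md.normalize_adjacency(np.zeros((5, 5), dtype=int)),
                                   np.eye(5))

    def test_single_edge_gives_half_everywhere(self):
        adj = np.array([[0, 1], [1, 0]])
        np.testing.assert_allclose(md.normalize_adjacency(adj), np.full((2, 2), 0.5))

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetric_with_spectrum_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(rng, int(rng.integers(2, 12)))
        norm = md.normalize_adjacency(adj)
        np.testing.assert_allclose(norm, norm.T)
        eigs = np.linalg.eigvalsh(norm)
        assert eigs.min() >= -1 - 1e-10 and eigs.max() <= 1 + 1e-10


class TestGCNForward:
    def test_identity_operator_preserves_nonnegative_embeddings(self):
        h = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        out = md.gcn_forward(np.eye(4), h, np.eye(3), ad.relu)
        np.testing.assert_allclose(out.value, h)

    def test_zero_weight_gives_zero_output(self):
        rng = np.random.default_rng(1)
        out = md.gcn_forward(np.eye(3), rng.normal(size=(3, 2)), np.zeros((2, 2)), ad.relu)
        assert np.all(out.value == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            md.gcn_forward(np.eye(3), np.zeros((3, 2)), np.zeros((3, 2)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_triple_product(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        adj = random_adjacency(rng, n)
        norm = md.normalize_adjacency(adj)
        h = rng.normal(size=(n, 4))
        w = rng.normal(size=(4, 3))
        out = md.gcn_forward(norm, h, w, ad.relu)
        expected = np.maximum(norm @ h @ w, 0.0)
        np.testing.assert_allclose(out.value, expected, atol=1e-12)


class TestSummarizeEmbeddings:
    def test_zero_embeddings_summarize_to_zero(self):
        p = np.ones((3, 1))
        out = md.summarize_embeddings(np.zeros((5, 3)), p, 2)
        assert np.all(out.value == 0)

    def test_top_k_matches_brute_force(self):
        rng = np.random.default_rng(4)
        h = rng.normal(size=(6, 3))
        p = rng.normal(size=(3, 1))
        out = md.summarize_embeddings(h, p, 2).value
        # ten-line oracle
        y = (h @ p).ravel() / np.linalg.norm(p)
        idx = np.argsort(-y, kind="stable")[:2]
        expected = h[idx] * np.tanh(y[idx])[:, None]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_pads_when_fewer_rows_than_k(self):
        rng = np.random.default_rng(5)
        h = rng.normal(size=(3, 2))
        out = md.summarize_embeddings(h, np.ones((2, 1)), 5).value
        assert out.shape == (5, 2)
        assert np.all(out[3:] == 0)


class TestGRUWeightUpdate:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d, m = 4, 3
        params = make_gru_params(rng, d)
        summary = rng.normal(size=(d, m))
        prev = rng.normal(size=(d, m))
        new, gates = md.gru_weight_update(ad.constant(summary), ad.constant(prev), params, 0)
        expected, z, r, cand = scalar_gru_oracle(
            summary, prev,
            *[params[f"gru0_{g}"].value for g in
              ("UZ", "CZ", "BZ", "UR", "CR", "BR", "UW", "CW", "BW")])
        np.testing.assert_allclose(new.value, expected, atol=1e-6)
        np.testing.assert_allclose(gates["update"].value, z, atol=1e-6)
        np.testing.assert_allclose(gates["reset"].value, r, atol=1e-6)
        np.testing.assert_allclose(gates["candidate"].value, cand, atol=1e-6)

    def test_update_gate_saturation_limits(self):
        rng = np.random.default_rng(9)
        d = 3
        prev = rng.normal(size=(d, d))
        summary = rng.normal(size=(d, d))
        for bias, toward_candidate in ((40.0, True), (-40.0, False)):
            params = make_gru_params(rng, d)
            params["gru0_BZ"] = ad.constant(np.full((d, 1), bias))
            new, gates = md.gru_weight_update(ad.constant(summary), ad.constant(prev),
                                              params, 0)
            if toward_candidate:
                np.testing.assert_allclose(new.value, gates["candidate"].value, atol=1e-8)
            else:
                np.testing.assert_allclose(new.value, prev, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_gate_ranges_and_convexity(self, seed):
        rng = np.random.default_rng(seed)
        d = 4
        params = make_gru_params(rng, d)
        summary = rng.normal(size=(d, d))
        prev = rng.normal(size=(d, d))
        new, gates = md.gru_weight_update(ad.constant(summary), ad.constant(prev), params, 0)
        assert np.all((gates["update"].value > 0) & (gates["update"].value < 1))
        assert np.all((gates["reset"].value > 0) & (gates["reset"].value < 1))
        assert np.all(np.abs(gates["candidate"].value) < 1)
        lo = np.minimum(prev, gates["candidate"].value)
        hi = np.maximum(prev, gates["candidate"].value)
        assert np.all(new.value >= lo - 1e-12) and np.all(new.value <= hi + 1e-12)


def build_forward_inputs(adjs, config_seed=0, dims_hidden=(5, 4)):
    seq = sequence_from_adjacencies(adjs, age_min=50)
    scores = [snapshot_scores(s) for s in seq]
    vocab = build_vocabulary(scores)
    feats = [one_hot_encode(s, vocab) for s in scores]
    norm = [md.normalize_adjacency(s) for s in seq]
    config = md.ModelConfig(dims=[vocab.d, *dims_hidden], seed=config_seed)
    params = md.init_parameters(config)
    return seq, feats, norm, config, params


class TestForwardSequence:
    def _random_adjs(self, seed, n_ages=3, n=5):
        rng = np.random.default_rng(seed)
        return [random_adjacency(rng, n) for _ in range(n_ages)]

    def test_bit_stable_across_runs(self):
        adjs = self._random_adjs(0)
        _, feats, norm, config, _ = build_forward_inputs(adjs)
        out1 = md.forward_sequence(norm, feats, md.init_parameters(config), config)
        out2 = md.forward_sequence(norm, feats, md.init_parameters(config), config)
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a.value, b.value)

    def test_length_mismatch_rejected(self):
        adjs = self._random_adjs(1)
        _, feats, norm, config, params = build_forward_inputs(adjs)
        with pytest.raises(ValueError):
            md.forward_sequence(norm, feats[:-1], params, config)

    def test_single_snapshot_is_one_gru_step_of_static_gcn(self):
        adjs = self._random_adjs(2, n_ages=1)
        _, feats, norm, config, params = build_forward_inputs(adjs)
        out = md.forward_sequence(norm, feats, params, config)
        assert len(out) == 1
        # manual single step
        h = ad.constant(feats[0])
        w = {l: params[f"W0_{l}"] for l in range(config.n_layers)}
        for l in range(config.n_layers):
            summary = md.summarize_embeddings(h, params[f"pool_p_{l}"],
                                              config.dims[l + 1]).T
            w[l], _ = md.gru_weight_update(summary, w[l], params, l)
            h = md.gcn_forward(ad.constant(norm[0]), h, w[l], config.layer_activation(l))
        np.testing.assert_allclose(out[0].value, h.value, atol=1e-12)

    def test_repeated_snapshots_stay_bounded(self):
        adjs = [self._random_adjs(3, n_ages=1)[0]] * 30
        _, feats, norm, config, params = build_forward_inputs(adjs)
        out = md.forward_sequence(norm, feats, params, config)
        assert all(np.isfinite(h.value).all() for h in out)
        assert max(np.abs(h.value).max() for h in out) < 1e3

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        n = 6
        adjs = [random_adjacency(rng, n) for _ in range(3)]
        seq, feats, norm, config, params = build_forward_inputs(adjs)
        out = md.forward_sequence(norm, feats, params, config)
        perm = rng.permutation(n)
        adjs_p = [a[np.ix_(perm, perm)] for a in adjs]
        norm_p = [md.normalize_adjacency(a) for a in adjs_p]
        feats_p = [f[perm] for f in feats]
        out_p = md.forward_sequence(norm_p, feats_p, params, config)
        for h, hp in zip(out, out_p):
            np.testing.assert_allclose(hp.value, h.value[perm], atol=1e-8)


class TestScorePairs:
    def _params(self, h=2, hidden=2, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "mlp_W1": ad.constant(rng.normal(size=(2 * h, hidden))),
            "mlp_b1": ad.constant(np.zeros((1, hidden))),
            "mlp_W2": ad.constant(rng.normal(size=(hidden, 1))),
            "mlp_b2": ad.constant(np.zeros((1, 1))),
        }

    def test_scores_are_exactly_symmetric(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(5, 2))
        params = self._params()
        s_ij = md.score_pairs(h, [(0, 3)], params).value
        s_ji = md.score_pairs(h, [(3, 0)], params).value
        assert s_ij[0] == s_ji[0]

    def test_self_pairs_rejected(self):
        with pytest.raises(ValueError):
            md.score_pairs(np.zeros((3, 2)), [(1, 1)], self._params())

    def test_hand_computed_two_unit_mlp(self):
        # 2-dim embeddings, 2 hidden units, hand-set weights
        h = np.array([[1.0, 0.0], [0.0, 1.0]])
        params = {
            "mlp_W1": ad.constant(np.array([[1.0, 0.0], [0.0, 1.0],
                                            [1.0, 1.0], [0.0, -1.0]])),
            "mlp_b1": ad.constant(np.zeros((1, 2))),
            "mlp_W2": ad.constant(np.array([[1.0], [2.0]])),
            "mlp_b2": ad.constant(np.array([[0.5]])),
        }
        # order (0,1): rep [1,0,0,1] -> relu([1,-1]) = [1,0] -> 1*1 + 0*2 + 0.5 = 1.5
        # order (1,0): rep [0,1,1,0] -> relu([1, 2]) = [1,2] -> 1*1 + 2*2 + 0.5 = 5.5
        # symmetrized mean: 3.5
        out = md.score_pairs(h, [(0, 1)], params).value
        np.testing.assert_allclose(out, [3.5])

    def test_score_depends_only_on_embeddings(self):
        params = self._params(seed=3)
        h1 = np.array([[1.0, 2.0], [0.5, -1.0], [1.0, 2.0]])
        s_02 = md.score_pairs(h1, [(0, 1)], params).value
        s_21 = md.score_pairs(h1, [(2, 1)], params).value  # same embedding as node 0
        np.testing.assert_allclose(s_02, s_21)


class TestLinkLoss:
    def test_zero_logits_give_ln2(self):
        loss = md.link_loss(np.zeros(8), np.array([1, 0] * 4), pos_weight=1.0)
        np.testing.assert_allclose(loss.item(), np.log(2.0), atol=1e-12)

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        logits = np.array([50.0, -50.0, 50.0])
        labels = np.array([1, 0, 1])
        assert md.link_loss(logits, labels, 1.0).item() < 1e-15

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=20)
        labels = (rng.random(20) < 0.3).astype(float)
        pw = 7.5
        expected = np.mean([
            pw * y * np.log1p(np.exp(-z)) + (1 - y) * np.log1p(np.exp(z))
            for z, y in zip(logits, labels)])
        np.testing.assert_allclose(md.link_loss(logits, labels, pw).item(),
                                   expected, atol=1e-7)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            md.link_loss(np.array([]), np.array([]), 1.0)
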