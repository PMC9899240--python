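"""Encoder components: positional encoding, masking, InfoNCE, training."""

import numpy as np
import pytest

import metastagraph.autodiff as ad
from metastagraph.autodiff import Tensor
from metastagraph.graphgen import TimeEvolvingGraph
from metastagraph.model import (GraphContrastiveEmbedder, attention_mask,
                                info_nce_loss, positional_encoding)


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = positional_encoding(4, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_first_entry_is_sin_one(self):
        pe = positional_encoding(4, 8)
        assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)
        assert pe[1, 1] == pytest.approx(np.cos(1.0), abs=1e-12)

    def test_entries_bounded(self):
        pe = positional_encoding(50, 16)
        assert np.all(np.abs(pe) <= 1.0)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 7)


class TestAttentionMask:
    def test_empty_graph(self):
        mask = attention_mask(np.zeros((3, 3), dtype=int))
        expect = np.eye(4, dtype=bool)
        expect[0, :] = expect[:, 0] = True
        np.testing.assert_array_equal(mask, expect)

    def test_complete_graph_all_ones(self):
        A = ~np.eye(4, dtype=bool)
        assert attention_mask(A).all()

    def test_path_graph_ones_count(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        mask = attention_mask(A)
        # non-master block: 3 self-connections + 2 symmetric edges = 7 ones
        assert mask[1:, 1:].sum() == 7

    def test_asymmetric_rejected(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = 1
        with pytest.raises(ValueError):
            attention_mask(A)


class TestInfoNCE:
    def test_identical_embeddings_log_b(self):
        for B in (2, 5, 64):
            batch = np.ones((B, 4))
            loss = info_nce_loss(batch[0], batch[0], batch, tau=1.0)
            assert loss == pytest.approx(np.log(B), abs=1e-8)

    def test_hand_computed_two_candidates(self):
        # query (1,0), positive (1,0), negative (-1,0), tau=1:
        # loss = -log(e / (e + 1/e))
        batch = np.array([[1.0, 0.0], [-1.0, 0.0]])
        loss = info_nce_loss(np.array([1.0, 0.0]), batch[0], batch, tau=1.0)
        expect = -np.log(np.e / (np.e + np.exp(-1.0)))
        assert loss == pytest.approx(expect, abs=1e-8)
        assert loss == pytest.approx(0.126928011, abs=1e-6)

    def test_loss_decreases_as_positive_similarity_grows(self):
        rng = np.random.default_rng(0)
        batch = rng.normal(size=(6, 3))
        q = rng.normal(size=3)
        losses = []
        for scale in (0.5, 1.0, 2.0):
            b = batch.copy()
            b[2] = q * scale  # positive increasingly aligned
            losses.append(info_nce_loss(q, b[2], b, tau=1.0))
        assert losses[0] > losses[1] > losses[2]

    def test_temperature_validation(self):
        with pytest.raises(ValueError):
            info_nce_loss(np.ones(2), np.ones(2), np.ones((3, 2)), tau=0.0)

    def test_batched_training_loss_matches_reference(self):
        """The vectorised in-batch loss equals the single-anchor formula with
        the candidate set {positive} ∪ {batch anchor embeddings}."""
        rng = np.random.default_rng(1)
        B, d, tau = 7, 3, 0.7
        g_t = rng.normal(size=(B, d))
        g_pos = rng.normal(size=(B, d))
        ad.set_dtype(np.float64)
        try:
            s_pos = ((Tensor(g_t) * Tensor(g_pos)).sum(axis=1) * (1.0 / tau)).reshape(B, 1)
            den = (Tensor(g_t) @ Tensor(g_t).transpose(1, 0)) * (1.0 / tau)
            logits = ad.concat([s_pos, den], axis=1)
            loss = -(logits.log_softmax()[:, 0].mean())
            reference = np.mean([
                info_nce_loss(g_t[i], g_pos[i], np.vstack([g_pos[i][None], g_t]), tau)
                for i in range(B)
            ])
            assert loss.item() == pytest.approx(reference, abs=1e-10)
        finally:
            ad.set_dtype(np.float32)


def tiny_model(**kw):
    defaults = dict(d=4, d_m=8, n_heads=2, n_layers=2, window_l=2, batch_size=8,
                    epochs=2, steps_per_epoch=2, feature_mode="degree", seed=0)
    defaults.update(kw)
    return GraphContrastiveEmbedder(**defaults)


def random_graph(T=40, n=9, seed=0, p=0.4):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((T, n, n)) < p, 1)
    snaps = upper | np.swapaxes(upper, 1, 2)
    return TimeEvolvingGraph(snaps)


class TestEncoder:
    def test_masked_attention_weights_exactly_zero(self):
        g = random_graph(T=10, n=7, seed=2, p=0.3)
        m = tiny_model().fit(g)
        data = m._prepare(g)
        capture = []
        m._forward_window(data, np.array([3]), capture=capture)
        A = g.snapshots[3]
        allowed = np.zeros((8, 8), dtype=bool)
        allowed[0, :] = allowed[:, 0] = True
        allowed[1:, 1:] = A
        np.fill_diagonal(allowed, True)
        for attn in capture:
            w = attn.data[0]  # (H, N, N)
            assert np.abs(w[:, ~allowed]).max() == 0.0
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-5)

    def test_permutation_invariance_constant_features(self):
        g = random_graph(T=12, n=8, seed=3)
        m = tiny_model(feature_mode="constant", use_positional_encoding=False).fit(g)
        emb = m.transform(g)
        perm = np.random.default_rng(0).permutation(8)
        snaps_p = g.snapshots[:, perm][:, :, perm]
        emb_p = m.transform(TimeEvolvingGraph(snaps_p))
        np.testing.assert_allclose(emb, emb_p, atol=1e-5)

    def test_inference_deterministic(self):
        g = random_graph()
        m = tiny_model().fit(g)
        np.testing.assert_array_equal(m.transform(g), m.transform(g))

    def test_output_shape_and_finite(self):
        g = random_graph(T=25, n=6)
        m = tiny_model(d=3).fit(g)
        emb = m.transform(g)
        assert emb.shape == (25, 3)
        assert np.isfinite(emb).all()

    def test_gradient_flows_to_all_parameters(self):
        g = random_graph(T=15, n=6, seed=5)
        m = tiny_model()
        m.fit(g)
        data = m._prepare(g)
        gt, gp = m._forward_window(data, np.array([2, 5, 8]), with_positive=True)
        logits = (gt @ gp.transpose(1, 0))
        eye = np.arange(3)
        loss = -(logits.log_softmax()[eye, eye].mean())
        for p in m.params_.values():
            p.zero_grad()
        loss.backward()
        for name, p in m.params_.items():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
        # generic inputs give nonzero encoder gradients
        assert np.abs(m.params_["L0_Wq"].grad).max() > 0


class TestTraining:
    def test_fixed_seed_identical_loss_curve(self):
        g = random_graph(T=30, n=6, seed=6)
        a = tiny_model(epochs=3).fit(g)
        b = tiny_model(epochs=3).fit(g)
        assert a.loss_curve_ == b.loss_curve_

    def test_loss_decreases_on_separable_data(self, alternating_graph, tiny_trained_model):
        m = tiny_trained_model
        assert m.loss_curve_[-1] < m.loss_curve_[0] - 0.2

    def test_embeddings_separate_planted_states(self, alternating_graph, tiny_trained_model):
        from sklearn.linear_model import LogisticRegression
        emb = tiny_trained_model.transform(alternating_graph)
        states = alternating_graph.states
        clf = LogisticRegression(max_iter=1000).fit(emb[:160], states[:160])
        assert clf.score(emb[160:], states[160:]) > 0.9

    def test_too_short_sequence_rejected(self):
        g = random_graph(T=3, n=5)
        with pytest.raises(ValueError):
            tiny_model(window_l=3).fit(g)

    def test_node_count_mismatch_rejected(self):
        m = tiny_model().fit(random_graph(T=20, n=6))
        with pytest.raises(ValueError):
            m.transform(random_graph(T=5, n=7))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GraphContrastiveEmbedder(d_m=10, n_heads=4).fit(random_graph())
        with pytest.raises(ValueError):
            GraphContrastiveEmbedder(tau=-1.0).fit(random_graph())

    def test_sklearn_get_set_params_roundtrip(self):
        m = tiny_model()
        params = m.get_params()
        m2 = GraphContrastiveEmbedder(**params)
        assert m2.get_params() == params
        m2.set_params(tau=0.5)
        assert m2.tau == 0.5


def test_save_load_roundtrip(tmp_path, tiny_trained_model, alternating_graph):
    path = tmp_path / "model.npz"
    tiny_trained_model.save(path)
    back = GraphContrastiveEmbedder.load(path)
    np.testing.assert_array_equal(back.transform(alternating_graph),
                                  tiny_trained_model.transform(alternating_graph))
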