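"""Encoder numerics: embeddings, attention stack, heads, gradients."""

import numpy as np
import pytest

from _oracles import finite_difference_gradient
from phalife.model import ModelConfig, ProteinBert


@pytest.fixture
def tiny():
    cfg = ModelConfig(vocab_size=7, d_model=4, n_layers=1, n_heads=2,
                      max_len=12, ffn_dim=8, dropout=0.0)
    return ProteinBert(cfg, seed=3)


def random_batch(cfg, B, seed=0):
    rng = np.random.default_rng(seed)
    L = cfg.max_len
    attn = rng.integers(3, L, size=B)
    ids = np.zeros((B, L), dtype=np.int64)
    for i in range(B):
        n = attn[i] - 2
        ids[i, 0] = 2
        ids[i, 1:1 + n] = rng.integers(5, cfg.vocab_size, size=n)
        ids[i, 1 + n] = 3
    return ids, attn


class TestEmbed:
    def test_zero_tables_give_zero_matrix(self, tiny):
        tiny.params["tok_emb"][:] = 0
        tiny.params["pos_emb"][:] = 0
        X = tiny.embed(_sentence(tiny, [5, 6]).token_ids)
        assert np.all(X == 0)

    def test_zero_position_table_makes_equal_tokens_equal_rows(self, tiny):
        tiny.params["pos_emb"][:] = 0
        X = tiny.embed(_sentence(tiny, [5, 5, 6]).token_ids)
        assert np.array_equal(X[1], X[2])
        assert not np.array_equal(X[1], X[3])

    def test_matches_hand_computed_sums(self, tiny):
        cfg = tiny.config
        tok = np.arange(cfg.vocab_size * 4, dtype=float).reshape(-1, 4)
        pos = np.arange(cfg.max_len * 4, dtype=float).reshape(-1, 4) * 0.1
        tiny.params["tok_emb"] = tok
        tiny.params["pos_emb"] = pos
        s = _sentence(tiny, [5, 6])
        X = tiny.embed(s.token_ids)
        for i, t in enumerate(s.token_ids[:cfg.max_len]):
            assert np.allclose(X[i], tok[t] + pos[i])

    def test_out_of_vocabulary_token_names_position(self, tiny):
        s = _sentence(tiny, [5, 6])
        s.token_ids[2] = 99
        with pytest.raises(ValueError, match="99"):
            tiny.embed(s.token_ids)


def _sentence(model, tokens):
    """Raw (ids, attention_length) pair at the model's max_len."""
    L = model.config.max_len
    n = min(len(tokens), L - 2)
    ids = np.zeros(L, dtype=np.int64)
    ids[0] = 2
    ids[1:1 + n] = tokens[:n]
    ids[1 + n] = 3
    return _Sent(ids, n + 2)


class _Sent:
    def __init__(self, ids, attn):
        self.token_ids = ids
        self.attention_length = attn


class TestEncode:
    def test_output_shape_equals_input_shape(self, tiny):
        s = _sentence(tiny, [5, 6, 5])
        X = tiny.embed(s.token_ids)
        Y = tiny.encode(X, s.attention_length)
        assert Y.shape == X.shape

    def test_permutation_equivariance_without_positions(self):
        cfg = ModelConfig(vocab_size=12, d_model=8, n_layers=2, n_heads=2,
                          max_len=10, dropout=0.0)
        model = ProteinBert(cfg, seed=5)
        model.params["pos_emb"][:] = 0
        tokens = [5, 6, 7, 8, 9]
        perm = [2, 0, 4, 1, 3]
        s1 = _sentence(model, tokens)
        s2 = _sentence(model, [tokens[p] for p in perm])
        Y1 = model.encode(model.embed(s1.token_ids), s1.attention_length)
        Y2 = model.encode(model.embed(s2.token_ids), s2.attention_length)
        # content rows permute together with the tokens
        for out_pos, src in enumerate(perm):
            assert np.allclose(Y2[1 + out_pos], Y1[1 + src], atol=1e-10)

    def test_pad_positions_cannot_leak_into_content(self, tiny):
        s = _sentence(tiny, [5, 6])
        Y1 = model_forward(tiny, s)
        s.token_ids[s.attention_length + 2] = 6  # corrupt a [PAD] slot
        Y2 = model_forward(tiny, s)
        assert np.allclose(Y1[:s.attention_length], Y2[:s.attention_length])

    def test_nan_input_raises(self, tiny):
        s = _sentence(tiny, [5, 6])
        tiny.params["tok_emb"][5, 0] = np.inf
        with np.errstate(invalid="ignore"), pytest.raises(FloatingPointError):
            model_forward(tiny, s)

    def test_eval_forward_is_deterministic_despite_dropout_config(self):
        cfg = ModelConfig(vocab_size=9, d_model=8, n_layers=1, n_heads=2,
                          max_len=10, dropout=0.5)
        model = ProteinBert(cfg, seed=1)
        s = _sentence(model, [5, 6, 7])
        assert np.array_equal(model_forward(model, s),
                              model_forward(model, s))


def model_forward(model, s):
    Y, _ = model._forward_batch(s.token_ids[None],
                                np.array([s.attention_length]))
    return Y[0]


class TestHeads:
    def test_mlm_rows_sum_to_one(self, tiny):
        s = _sentence(tiny, [5, 6, 5])
        Y = model_forward(tiny, s)
        probs = tiny.mlm_logits(Y, [1, 2, 3])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_projection_gives_uniform(self, tiny):
        tiny.params["mlm_w"][:] = 0
        s = _sentence(tiny, [5, 6])
        probs = tiny.mlm_logits(model_forward(tiny, s), [1])
        assert np.allclose(probs, 1.0 / tiny.config.vocab_size)

    def test_mlm_matches_hand_computed_softmax(self):
        cfg = ModelConfig(vocab_size=5, d_model=2, n_layers=1, n_heads=1,
                          max_len=6, dropout=0.0)
        model = ProteinBert(cfg, seed=0)
        W = np.array([[1.0, 0.0, -1.0, 0.5, 0.0],
                      [0.0, 2.0, 1.0, -0.5, 0.0]])
        model.params["mlm_w"] = W
        Y = np.zeros((6, 2))
        Y[1] = [0.3, -0.7]
        logits = Y[1] @ W
        expected = np.exp(logits) / np.exp(logits).sum()
        probs = model.mlm_logits(Y, [1])
        assert np.allclose(probs[0], expected)

    def test_cls_uniform_when_untrained_head_is_zero(self, tiny):
        tiny.params["cls_w"][:] = 0
        tiny.params["cls_b"][:] = 0
        s = _sentence(tiny, [5, 6])
        assert np.allclose(tiny.cls_probs(model_forward(tiny, s)), [0.5, 0.5])

    def test_cls_bias_only_closed_form(self, tiny):
        tiny.params["cls_w"][:] = 0
        tiny.params["cls_b"][:] = [np.log(3.0), 0.0]
        s = _sentence(tiny, [5, 6])
        assert np.allclose(tiny.cls_probs(model_forward(tiny, s)),
                           [0.75, 0.25])

    def test_cls_matches_hand_computation(self, tiny):
        Wp = np.array([[0.5, -0.5], [1.0, 0.0], [0.0, 1.0], [-1.0, 1.0]])
        bp = np.array([0.1, -0.2])
        tiny.params["cls_w"], tiny.params["cls_b"] = Wp, bp
        Y = np.zeros((12, 4))
        Y[0] = [1.0, -2.0, 0.5, 0.25]
        logits = Y[0] @ Wp + bp
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(tiny.cls_probs(Y), expected)
        assert tiny.cls_probs(Y).sum() == pytest.approx(1.0, abs=1e-6)


class TestPersistence:
    def test_save_load_reproduces_logits_bitwise(self, tmp_path, tiny):
        ids, attn = random_batch(tiny.config, 3, seed=2)
        before = tiny.predict_proba(ids, attn)
        path = tmp_path / "ckpt.npz"
        tiny.save(path)
        loaded = ProteinBert.load(path)
        after = loaded.predict_proba(ids, attn)
        assert np.array_equal(before, after)
        assert loaded.config == tiny.config


class TestGradients:
    """Analytic gradients vs central finite differences on a 1-layer model."""

    def assert_gradients_match(self, model, loss_and_grads, n_per_param=4):
        loss, grads = loss_and_grads()
        rng = np.random.default_rng(0)
        for key, p in model.params.items():
            for _ in range(n_per_param):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                num = finite_difference_gradient(
                    lambda: loss_and_grads()[0], model.params, key, idx)
                ana = grads[key][idx]
                scale = max(abs(num), abs(ana))
                if scale > 1e-6:
                    assert abs(num - ana) / scale < 1e-4, \
                        f"{key}{idx}: analytic {ana} vs numeric {num}"
                else:   # both effectively zero: difference is FD noise
                    assert abs(num - ana) < 1e-6

    def test_masked_lm_loss_gradients(self, tiny):
        ids, attn = random_batch(tiny.config, 3, seed=2)
        triple = (np.array([0, 0, 1, 2]), np.array([1, 3, 2, 5]),
                  np.array([5, 6, 5, 6]))
        self.assert_gradients_match(
            tiny, lambda: tiny.mlm_loss_and_grads(ids, attn, triple,
                                                  train=False))

    def test_classification_loss_gradients(self, tiny):
        ids, attn = random_batch(tiny.config, 3, seed=4)
        labels = np.array([0, 1, 0])
        self.assert_gradients_match(
            tiny, lambda: tiny.cls_loss_and_grads(ids, attn, labels,
                                                  train=False))


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(vocab_size=10, d_model=10, n_heads=3)
    with pytest.raises(ValueError):
        ModelConfig(vocab_size=0)
    cfg = ModelConfig.desk(100)
    assert (cfg.d_model, cfg.n_layers, cfg.n_heads) == (64, 2, 4)
    assert cfg.ffn_dim == 4 * cfg.d_model
    full = ModelConfig.paper_scale(100)
    assert (full.d_model, full.n_layers, full.n_heads) == (512, 8, 8)
    assert full.max_len == 300
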