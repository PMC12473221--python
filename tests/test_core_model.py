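"""Core model contracts: fusion, pooling, token order, attention, heads."""

import numpy as np
import pytest

from lmeran.autodiff import Tensor
from lmeran.backbones import StubBackbone, create_backbone
from lmeran.config import ModelConfig
from lmeran.masking import masked_bce_loss, MaskSpec
from lmeran.model import (
    AttentionLayerParams, LMeRAN, attention_layer, attention_stack,
    build_token_set, classify, combine_residual, fuse_label_state,
    global_pool, load_checkpoint, save_checkpoint,
)


# --------------------------------------------------------------- brute force
def attention_oracle(tokens, params, scale_mode="sqrt_head"):
    """Dense triple-loop multi-head self-attention, kept deliberately naive."""
    m, d = tokens.shape
    p = params.heads
    dh = d // p
    scale = 1.0 / d if scale_mode == "literal_d" else 1.0 / np.sqrt(dh)
    heads = []
    alphas = np.zeros((p, m, m))
    for t in range(p):
        wq, wk, wv = params.wq.data[t], params.wk.data[t], params.wv.data[t]
        out_t = np.zeros((m, dh))
        for i in range(m):
            scores = np.array([tokens[i] @ wq @ (tokens[j] @ wk) * scale
                               for j in range(m)])
            e = np.exp(scores - scores.max())
            alpha = e / e.sum()
            alphas[t, i] = alpha
            for j in range(m):
                out_t[i] += alpha[j] * (tokens[j] @ wv)
        heads.append(out_t)
    return np.concatenate(heads, axis=1) @ params.wo.data, alphas


# ------------------------------------------------------------------- fusion
def test_fuse_label_state_is_elementwise_sum():
    assert np.allclose(
        fuse_label_state(Tensor([1.0, 2.0]), Tensor([0.0, 0.0])).data, [1, 2])
    assert np.allclose(
        fuse_label_state(Tensor([1.0, -1.0]), Tensor([0.5, 0.5])).data,
        [1.5, -0.5])


def test_fuse_subtraction_recovers_label(rng):
    l = rng.normal(size=8)
    s = rng.normal(size=8)
    c = fuse_label_state(Tensor(l), Tensor(s))
    assert np.allclose(c.data - s, l)


def test_fuse_depth_mismatch_rejected():
    with pytest.raises(ValueError):
        fuse_label_state(Tensor([1.0, 2.0]), Tensor([1.0, 2.0, 3.0]))


# ------------------------------------------------------------------- pooling
def test_global_pool_of_constant_map_is_the_constant(rng):
    v = rng.normal(size=4)
    fmap = Tensor(np.tile(v, (9, 1)))
    assert np.allclose(global_pool(fmap).data, v)


def test_global_pool_matches_mean_oracle():
    fmap = Tensor(np.array([[0.0], [2.0], [4.0], [6.0]]))
    assert np.allclose(global_pool(fmap).data, [3.0], atol=1e-6)
    single = Tensor(np.array([[1.5, -2.0]]))
    assert np.allclose(global_pool(single).data, [1.5, -2.0])


# ----------------------------------------------------------------- token set
def test_token_set_order_and_size(rng):
    fmap = Tensor(rng.normal(size=(4, 5)))      # h=w=2
    labels = Tensor(rng.normal(size=(3, 5)))
    tokens = build_token_set(fmap, labels)
    assert tokens.shape == (7, 5)
    for i in range(3):
        assert np.allclose(tokens.data[4 + i], labels.data[i])
    with pytest.raises(ValueError):
        build_token_set(fmap, Tensor(np.empty((0, 5))))
    with pytest.raises(ValueError):
        build_token_set(fmap, Tensor(rng.normal(size=(3, 4))))


# ----------------------------------------------------------------- attention
def test_attention_singleton_with_identity_maps_returns_input():
    d = 4
    params = AttentionLayerParams(
        wq=Tensor(np.zeros((1, d, d))), wk=Tensor(np.zeros((1, d, d))),
        wv=Tensor(np.eye(d)[None]), wo=Tensor(np.eye(d)))
    token = np.array([[1.0, -2.0, 0.5, 3.0]])
    out, alpha = attention_layer(Tensor(token), params)
    assert np.allclose(alpha.data, 1.0)
    assert np.allclose(out.data[0], token)


def test_attention_identical_tokens_split_weight_evenly(rng):
    d, p = 6, 2
    params = AttentionLayerParams.init(d, p, rng)
    token = rng.normal(size=d)
    tokens = Tensor(np.stack([token, token]))
    _, alpha = attention_layer(tokens, params)
    assert np.allclose(alpha.data, 0.5, atol=1e-12)


@pytest.mark.parametrize("scale_mode", ["sqrt_head", "literal_d"])
@pytest.mark.parametrize("p", [1, 2])
def test_attention_matches_bruteforce_oracle(rng, p, scale_mode):
    for _ in range(10):
        m = int(rng.integers(2, 9))
        d = int(rng.choice([4, 8]))
        tokens = rng.normal(size=(m, d))
        params = AttentionLayerParams.init(d, p, rng)
        out, alpha = attention_layer(Tensor(tokens), params,
                                     scale_mode=scale_mode)
        exp_out, exp_alpha = attention_oracle(tokens, params, scale_mode)
        assert np.allclose(out.data[0], exp_out, atol=1e-5)
        assert np.allclose(alpha.data[0], exp_alpha, atol=1e-5)


def test_attention_rows_sum_to_one_through_stack(rng):
    layers = [AttentionLayerParams.init(8, 4, rng) for _ in range(3)]
    tokens = Tensor(rng.normal(size=(2, 6, 8)))
    _, alphas = attention_stack(tokens, layers)
    for alpha in alphas:
        assert np.allclose(alpha.data.sum(axis=-1), 1.0, atol=1e-6)


def test_attention_stack_shape_conserved_and_layer_local(rng):
    d = 8
    layers = [AttentionLayerParams.init(d, 2, rng) for _ in range(2)]
    tokens = Tensor(rng.normal(size=(1, 5, d)))
    out1, _ = attention_layer(tokens, layers[0])
    out_stack, alphas = attention_stack(tokens, layers)
    assert out_stack.shape == tokens.shape
    assert len(alphas) == 2
    # perturbing layer-2 parameters changes the stack output but leaves the
    # layer-1 output untouched
    layers[1].wo.data = layers[1].wo.data + 0.5
    out_stack2, _ = attention_stack(tokens, layers)
    out1_again, _ = attention_layer(tokens, layers[0])
    assert not np.allclose(out_stack.data, out_stack2.data)
    assert np.allclose(out1.data, out1_again.data)
    with pytest.raises(ValueError):
        attention_stack(tokens, [])


def test_attention_rejects_indivisible_heads(rng):
    with pytest.raises(ValueError):
        AttentionLayerParams.init(6, 4, rng)


# ------------------------------------------------------------------ residual
def test_combine_residual_cases():
    g = Tensor(np.array([1.0, 1.0]))
    r = Tensor(np.array([[1.0, -1.0], [0.5, 0.5]]))
    z = combine_residual(g, r, 0.2)
    assert np.allclose(z.data[0], [1.2, 0.8])
    z0 = combine_residual(g, r, 0.0)
    assert np.allclose(z0.data, np.tile(g.data, (2, 1)))
    z1 = combine_residual(Tensor(np.zeros(2)), r, 1.0)
    assert np.allclose(z1.data, r.data)
    with pytest.raises(ValueError):
        combine_residual(g, Tensor(np.zeros((2, 3))), 0.2)


# ---------------------------------------------------------------- classifier
def test_classify_closed_forms(rng):
    d = 4
    z = Tensor(rng.normal(size=(1, d)))
    assert np.allclose(
        classify(z, Tensor(np.zeros((1, d))), Tensor(np.zeros(1))).data, 0.5)
    # w.z + b = ln 3  ->  sigmoid = 0.75
    w = Tensor(np.ones((1, d)))
    b = Tensor(np.array([np.log(3.0) - float(z.data.sum())]))
    assert np.allclose(classify(z, w, b).data, 0.75, atol=1e-12)
    b_sat = Tensor(np.array([20.0 - float(z.data.sum())]))
    assert classify(z, w, b_sat).data[0] > 0.999


# ------------------------------------------------------------------- forward
def test_forward_deterministic_in_eval_mode(tiny_model, rng):
    images = rng.random((2, 56, 56))
    states = np.zeros((2, 6), dtype=int)
    p1 = tiny_model.forward(images, states).data
    p2 = tiny_model.forward(images, states).data
    assert np.array_equal(p1, p2)
    assert ((p1 > 0) & (p1 < 1)).all()


def test_forward_state_change_couples_labels(tiny_model, rng):
    images = rng.random((1, 56, 56))
    states = np.zeros((1, 6), dtype=int)
    base = tiny_model.forward(images, states).data
    states2 = states.copy()
    states2[0, 3] = 2  # label 3: unknown -> positive
    moved = tiny_model.forward(images, states2).data
    others = [j for j in range(6) if j != 3]
    assert not np.allclose(base[0, others], moved[0, others])


def test_forward_lambda_zero_ignores_residuals(rng):
    cfg = ModelConfig(backbone="tiny", input_size=56,
                      labels=[f"L{i}" for i in range(4)], heads=2, layers=2,
                      lam=0.0)
    model = LMeRAN(cfg, rng=3)
    images = rng.random((2, 56, 56))
    base = model.forward(images, np.zeros((2, 4), dtype=int)).data
    # with lam = 0 the states (which only enter through the residual
    # tokens) cannot influence the prediction
    states = np.full((2, 4), 2, dtype=int)
    assert np.allclose(model.forward(images, states).data, base)


def test_forward_rejects_bad_states(tiny_model, rng):
    images = rng.random((1, 56, 56))
    with pytest.raises(ValueError):
        tiny_model.forward(images, np.zeros((1, 5), dtype=int))
    with pytest.raises(ValueError):
        tiny_model.forward(images, np.array([["mystery"] * 6]))


def test_gradient_reaches_label_embeddings_only_with_residual(rng):
    for lam, expect_grad in [(0.2, True), (0.0, False)]:
        cfg = ModelConfig(backbone="tiny", input_size=56,
                          labels=["A", "B", "C"], heads=2, layers=1, lam=lam)
        model = LMeRAN(cfg, rng=1)
        images = rng.random((2, 56, 56))
        y = rng.integers(0, 2, size=(2, 3))
        probs = model.forward(images, np.zeros((2, 3), dtype=int))
        loss = masked_bce_loss(probs, y, MaskSpec(n=3, masked=frozenset({0, 1, 2})))
        loss.backward()
        grad_norm = np.abs(model.label_emb.grad).max() \
            if model.label_emb.grad is not None else 0.0
        if expect_grad:
            assert grad_norm > 1e-12
        else:
            assert grad_norm == 0.0


# ------------------------------------------------------------------ backbone
def test_stub_backbone_constant_features(rng):
    model = LMeRAN(
        ModelConfig(backbone="stub", input_size=16, labels=["A", "B"],
                    heads=2, layers=1),
        rng=0, backbone=StubBackbone(h=2, w=2, d=4, value=0.7))
    fmap = model.extract_features(rng.random((1, 16, 16)))
    assert np.allclose(fmap.data, 0.7)


def test_tiny_backbone_grid_shape():
    bb = create_backbone("tiny", np.random.default_rng(0))
    assert bb.grid_shape(56) == (7, 7)
    out = bb.forward(np.random.default_rng(1).random((2, 56, 56)))
    assert out.shape == (2, 49, 32)


def test_dense_backbone_stride32_shape_contract():
    bb = create_backbone("densenet121", np.random.default_rng(0))
    assert bb.grid_shape(448) == (14, 14)
    out = bb.forward(np.random.default_rng(1).random((1, 448, 448)))
    assert out.shape == (1, 14 * 14, 1024)
    assert np.isfinite(out.data).all()


def test_unknown_backbone_rejected():
    with pytest.raises(ValueError):
        create_backbone("resnet9000")


# ---------------------------------------------------------------- checkpoint
def test_checkpoint_roundtrip(tmp_path, tiny_model, rng):
    images = rng.random((2, 56, 56))
    states = np.zeros((2, 6), dtype=int)
    before = tiny_model.forward(images, states).data
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path)
    restored = load_checkpoint(path)
    assert restored.labels == tiny_model.labels
    assert np.allclose(restored.forward(images, states).data, before)
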