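"""Network components vs. brute-force oracles, plus end-to-end contracts."""

import numpy as np
import pytest

from gatan.autodiff import Tensor
from gatan.model import (GATAN, EMABlock, Grapher, ModelConfig, MSGA,
                         VariableWindowAttention, WindowSpec, build_check,
                         merge_windows, partition_windows, upsample2,
                         window_mask, ConfigError)

rng = np.random.default_rng(7)


def tiny_config(**kw):
    base = dict(n_classes=2, patch_shape=(32, 32, 32), channels=(8, 16),
                depths=(2, 2), cubic_window=(4, 4), stripe_thickness=(4, 4),
                heads=(1, 1), graph_k=4, task="octa")
    base.update(kw)
    return ModelConfig(**base)


# -- window partitioning ----------------------------------------------------

def test_partition_counts_and_inverse_identity():
    x = rng.normal(size=(2, 8, 8, 8, 4)).astype(np.float32)
    for spec in (WindowSpec((4, 4, 4)), WindowSpec((4, 4, 4), shifted=True),
                 WindowSpec((4, -1, 4)), WindowSpec((-1, 4, 4), shifted=True)):
        xw, mask, meta = partition_windows(Tensor(x), spec)
        w = [8 if s == -1 else s for s in spec.shape]
        n_windows = int(np.prod([8 // wi for wi in w]))
        assert xw.shape == (2, n_windows, int(np.prod(w)), 4)
        back = merge_windows(xw, meta)
        assert np.array_equal(back.data, x)
    # 8^3 volume, cubic window 4, unshifted: 8 windows of 64 tokens
    xw, mask, _ = partition_windows(Tensor(x), WindowSpec((4, 4, 4)))
    assert xw.shape[1] == 8 and xw.shape[2] == 64 and mask is None


def test_shifted_mask_matches_brute_force_region_pairs():
    """Oracle: tag every voxel with its pre-shift window id, roll the tags the
    same way, and forbid exactly the token pairs whose tags differ."""
    dims, w, s = (8, 8, 8), 4, 2
    spec = WindowSpec((4, 4, 4), shifted=True)
    mask = window_mask(dims, spec)
    ids = np.zeros(dims, dtype=int)
    for d in range(8):
        for h in range(8):
            for ww in range(8):
                ids[d, h, ww] = (d // w) * 4 + (h // w) * 2 + (ww // w)
    ids = np.roll(ids, (-s, -s, -s), axis=(0, 1, 2))
    # collect tokens window by window, in partition order
    tok = np.zeros((8, 64), dtype=int)
    for wi, (bd, bh, bw) in enumerate([(a, b, c) for a in range(2)
                                       for b in range(2) for c in range(2)]):
        block = ids[bd * 4:(bd + 1) * 4, bh * 4:(bh + 1) * 4, bw * 4:(bw + 1) * 4]
        tok[wi] = block.reshape(-1)
    for wi in range(8):
        for i in range(64):
            for j in range(64):
                expected = 0.0 if tok[wi, i] == tok[wi, j] else -1e9
                assert mask[wi, i, j] == expected


def test_unshifted_partition_has_no_mask_and_indivisible_dims_fail():
    assert window_mask((8, 8, 8), WindowSpec((4, 4, 4))) is None
    with pytest.raises(ConfigError, match="divisible"):
        partition_windows(Tensor(np.zeros((1, 6, 6, 6, 4))), WindowSpec((4, 4, 4)))


# -- attention --------------------------------------------------------------

def test_single_window_attention_matches_dense_oracle():
    """Windowed attention where the window covers the whole input must equal
    dense O(n^2) self-attention on the same q/k/v (shared weights)."""
    blk = VariableWindowAttention(8, heads=2, cubic=4, stripe=4,
                                  rng=np.random.default_rng(0))
    gd = 2  # one channel group
    q = rng.normal(size=(1, 4, 4, 4, gd)).astype(np.float32)
    k = rng.normal(size=(1, 4, 4, 4, gd)).astype(np.float32)
    v = rng.normal(size=(1, 4, 4, 4, gd)).astype(np.float32)
    got = blk._attend(Tensor(q), Tensor(k), Tensor(v), WindowSpec((4, 4, 4))).data

    # dense oracle with the same heads
    heads, hd = 2, 1
    qt = q.reshape(64, heads, hd).transpose(1, 0, 2)
    kt = k.reshape(64, heads, hd).transpose(1, 0, 2)
    vt = v.reshape(64, heads, hd).transpose(1, 0, 2)
    outs = []
    for h in range(heads):
        logits = qt[h] @ kt[h].T / np.sqrt(hd)
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        a = e / e.sum(axis=-1, keepdims=True)
        outs.append(a @ vt[h])
    dense = np.stack(outs, 1).reshape(1, 4, 4, 4, gd)
    assert np.allclose(got, dense, atol=1e-5)


def test_attention_block_zero_input_is_identity_and_batch_equivariant():
    blk = VariableWindowAttention(8, heads=1, cubic=4, stripe=4,
                                  rng=np.random.default_rng(1))
    z = np.zeros((1, 8, 4, 4, 4), np.float32)
    assert np.allclose(blk(Tensor(z)).data, z, atol=1e-7)

    x = rng.normal(size=(3, 8, 4, 4, 4)).astype(np.float32)
    out = blk(Tensor(x)).data
    perm = [2, 0, 1]
    out_p = blk(Tensor(x[perm])).data
    assert np.allclose(out[perm], out_p, atol=1e-6)


def test_stripe_window_token_cap_enforced():
    cfg = tiny_config(patch_shape=(32, 32, 32), stripe_token_cap=8)
    with pytest.raises(ConfigError, match="cap"):
        cfg.validate()  # stage 0 is 16 tokens along the unbounded axis


# -- EMA --------------------------------------------------------------------

def test_ema_shape_and_constant_input_gates():
    ema = EMABlock(16, np.random.default_rng(2))
    x = rng.normal(size=(2, 16, 8, 8, 8)).astype(np.float32)
    out = ema(Tensor(x)).data
    assert out.shape == x.shape
    const = np.full((1, 16, 6, 6, 6), 0.7, np.float32)
    oc = ema(Tensor(const)).data
    # axis pooling of a constant is constant -> spatially constant output
    assert np.allclose(oc, oc[:, :, :1, :1, :1], atol=1e-6)


def test_ema_gates_stay_in_sigmoid_range():
    """Exhaustive scan: the block is a reweighting by gates in (0,1), so it
    shrinks every voxel towards zero without flipping sign."""
    ema = EMABlock(8, np.random.default_rng(3))
    x = rng.normal(size=(1, 8, 5, 5, 5)).astype(np.float32)
    out = ema(Tensor(x)).data
    ratio = out[np.abs(x) > 1e-6] / x[np.abs(x) > 1e-6]
    assert (ratio > 0).all() and (ratio < 1).all()


# -- grapher ----------------------------------------------------------------

def test_knn_matches_exhaustive_ranking_on_4cubed_map():
    feats = rng.normal(size=(1, 64, 6)).astype(np.float32)
    k = 5
    idx = Grapher.knn_indices(feats, k)
    for n in range(64):
        d = np.linalg.norm(feats[0] - feats[0, n], axis=-1)
        d[n] = np.inf
        expected = set(np.argsort(d)[:k])
        assert set(idx[0, n].tolist()) == expected


def test_two_node_max_relative_update_matches_closed_form():
    g = Grapher(3, k=1, rng=np.random.default_rng(4))
    x = rng.normal(size=(1, 3, 1, 1, 2)).astype(np.float32)
    out = g(Tensor(x)).data.reshape(3, 2).T            # (2 nodes, 3 channels)
    nodes = x.reshape(3, 2).T
    W, b = g.fc.weight.data, g.fc.bias.data
    for n in range(2):
        msg = nodes[1 - n] - nodes[n]                  # the only neighbor
        expected = nodes[n] + np.concatenate([nodes[n], msg]) @ W + b
        assert np.allclose(out[n], expected, atol=1e-5)


def test_identical_nodes_leave_only_residual_path():
    g = Grapher(4, k=3, rng=np.random.default_rng(5))
    x = np.broadcast_to(rng.normal(size=(1, 4, 1, 1, 1)), (1, 4, 2, 2, 2)).astype(np.float32)
    out = g(Tensor(x.copy())).data
    node = x[0, :, 0, 0, 0]
    expected = node + np.concatenate([node, np.zeros(4)]) @ g.fc.weight.data + g.fc.bias.data
    assert np.allclose(out[0, :, 1, 1, 1], expected, atol=1e-5)
    with pytest.raises(ConfigError):
        Grapher(4, k=0, rng=np.random.default_rng(0))
    with pytest.raises(ConfigError):
        Grapher.knn_indices(np.zeros((1, 4, 2)), 4)


# -- MSGA -------------------------------------------------------------------

def test_msga_shape_contract_and_channel_arithmetic():
    r = np.random.default_rng(6)
    msga = MSGA((8, 16), graph_k=3, rng=r)
    pyr = [Tensor(rng.normal(size=(1, 8, 8, 8, 8)).astype(np.float32)),
           Tensor(rng.normal(size=(1, 16, 4, 4, 4)).astype(np.float32))]
    out = msga(pyr)
    assert [o.shape for o in out] == [p.shape for p in pyr]
    # concatenation channels: own graph + one aligned deeper level
    assert msga.refines[0].weight.shape[1] == 8 * 2
    assert msga.refines[1].weight.shape[1] == 16
    with pytest.raises(ValueError, match="batch"):
        msga([pyr[0], Tensor(np.zeros((2, 16, 4, 4, 4), np.float32))])


def test_msga_flag_bypasses_graph_parameters():
    """With use_msga off the forward output must not depend on any MSGA
    parameter (plain skip path, bit-identical)."""
    cfg = tiny_config(use_msga=False)
    model = GATAN(cfg, seed=0)
    x = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
    a = model(x).voxel_logits.data
    for _, p in model.msga.named_parameters():
        p.data = p.data + 1000.0
    b = model(x).voxel_logits.data
    assert np.array_equal(a, b)
    cfg_on = tiny_config(use_msga=True)
    m2 = GATAN(cfg_on, seed=0)
    c = m2(x).voxel_logits.data
    for _, p in m2.msga.named_parameters():
        p.data = p.data + 1.0
    d = m2(x).voxel_logits.data
    assert not np.array_equal(c, d)


# -- full network -----------------------------------------------------------

def test_forward_shape_contract_and_existence_pooling():
    model = GATAN(tiny_config(), seed=0)
    out = model(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
    assert out.voxel_logits.shape == (1, 2, 32, 32, 32)
    assert out.existence_logits.shape == (1, 8)  # 2x2x2 region grid

    cow = GATAN(tiny_config(n_classes=14, task="cow"), seed=0)
    o = cow(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
    assert o.existence_logits.shape == (1, 13)
    # existence logit for class c == spatial mean of that class's logit map
    means = o.voxel_logits.data[:, 1:].mean(axis=(2, 3, 4))
    assert np.allclose(o.existence_logits.data, means, atol=1e-6)


def test_gradient_reaches_every_parameter_group():
    model = GATAN(tiny_config(), seed=1)
    out = model(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
    loss = (out.voxel_logits * out.voxel_logits).sum() + \
           (out.existence_logits * out.existence_logits).sum()
    loss.backward()
    groups = {}
    for name, p in model.named_parameters():
        g = name.split(".")[0]
        groups.setdefault(g, False)
        if p.grad is not None and np.abs(p.grad).max() > 0:
            groups[g] = True
    for g in ("stem", "fullres", "stages", "emas", "msga", "downs", "up_projs",
              "merges", "final_conv", "head"):
        assert groups[g], f"no gradient reached parameter group {g}"


def test_determinism_same_seed_same_init_and_output():
    x = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
    a, b = GATAN(tiny_config(), seed=3), GATAN(tiny_config(), seed=3)
    sa, sb = a.state_dict(), b.state_dict()
    assert all(np.array_equal(sa[k], sb[k]) for k in sa)
    assert np.array_equal(a(x).voxel_logits.data, b(x).voxel_logits.data)


def test_config_validation_errors_and_build_check():
    with pytest.raises(ConfigError, match="divisible by 4"):
        tiny_config(channels=(6, 12)).validate()
    with pytest.raises(ConfigError, match="graph_k"):
        tiny_config(graph_k=0).validate()
    with pytest.raises(ConfigError, match="cubic"):
        tiny_config(cubic_window=(5, 5)).validate()
    build_check(tiny_config())  # passes: raises on shape inconsistency


def test_upsample2_is_nearest_neighbor():
    x = rng.normal(size=(1, 2, 2, 2, 2)).astype(np.float32)
    up = upsample2(Tensor(x)).data
    assert up.shape == (1, 2, 4, 4, 4)
    assert np.array_equal(up, np.repeat(np.repeat(np.repeat(x, 2, 2), 2, 3), 2, 4))
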