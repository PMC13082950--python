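"""Oracle and property tests for the topology-aware objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gatan.autodiff import Tensor
from gatan import losses as L
from gatan.losses import (AdjacencyGraph, LossWeights, cl_dice_loss,
                          connectivity_loss_mra, existence_loss_mra,
                          existence_loss_octa, grey_dilate, pixel_loss,
                          region_existence_labels, soft_skeletonize, total_loss)

from conftest import tube_mask

rng = np.random.default_rng(42)


# -- pixel loss -------------------------------------------------------------

def test_pixel_loss_uniform_logits_is_ln2():
    logits = np.zeros((1, 2, 3, 3, 3))
    labels = (rng.random((1, 3, 3, 3)) < 0.4).astype(int)
    labels[0, 0, 0, 0] = 1  # ensure some foreground
    assert pixel_loss(logits, labels).item() == pytest.approx(np.log(2), abs=1e-6)


def test_pixel_loss_saturates_with_large_margin():
    labels = rng.integers(0, 3, size=(1, 3, 3, 3))
    labels[0, 0, 0, 0] = 1
    logits = np.full((1, 3, 3, 3, 3), -10.0)
    for c in range(3):
        logits[0, c][labels[0] == c] = 10.0  # +20 margin for the true class
    assert pixel_loss(logits, labels).item() < 1e-8


def test_pixel_loss_matches_per_voxel_hand_sum():
    """Independent oracle: explicit softmax + log per voxel, summed in python."""
    C = 3
    logits = rng.normal(size=(1, C, 3, 3, 3))
    labels = rng.integers(0, C, size=(1, 3, 3, 3))
    labels[0, 1, 1, 1] = 1
    expected, n = 0.0, 0
    for d in range(3):
        for h in range(3):
            for w in range(3):
                y = labels[0, d, h, w]
                if y == 0:
                    continue
                z = logits[0, :, d, h, w]
                expected -= np.log(np.exp(z[y]) / np.exp(z).sum())
                n += 1
    assert pixel_loss(logits, labels).item() == pytest.approx(expected / n, rel=1e-5)


def test_pixel_loss_no_foreground_warns_and_returns_zero():
    with pytest.warns(UserWarning, match="no foreground"):
        out = pixel_loss(np.zeros((1, 2, 2, 2, 2)), np.zeros((1, 2, 2, 2), int))
    assert out.item() == 0.0


def test_pixel_loss_all_voxel_variant_includes_background():
    logits = np.zeros((1, 2, 2, 2, 2))
    labels = np.zeros((1, 2, 2, 2), int)
    labels[0, 0, 0, 0] = 1
    out = pixel_loss(logits, labels, ignore_background=False)
    assert out.item() == pytest.approx(np.log(2), abs=1e-6)


# -- existence losses -------------------------------------------------------

def test_existence_mra_zero_logits_and_limits():
    e = np.array([[1, 0, 1]])
    assert existence_loss_mra(np.zeros((1, 3)), e).item() == pytest.approx(np.log(2), abs=1e-6)
    assert existence_loss_mra(np.full((1, 1), 30.0), [[1]]).item() < 1e-8
    assert existence_loss_mra(np.full((1, 1), -30.0), [[1]]).item() == pytest.approx(30.0, rel=1e-4)
    with pytest.raises(ValueError, match="binary"):
        existence_loss_mra(np.zeros((1, 2)), [[0.5, 1.0]])


def test_existence_mra_matches_six_cell_hand_sum():
    g = rng.normal(size=(2, 3))
    e = rng.integers(0, 2, size=(2, 3))
    sig = 1 / (1 + np.exp(-g))
    expected = -(e * np.log(sig) + (1 - e) * np.log(1 - sig)).mean()
    assert existence_loss_mra(g, e).item() == pytest.approx(expected, rel=1e-5)


def test_region_labels_single_octant(octa_small):
    lab = np.zeros((16, 16, 16), np.int16)
    lab[2:6, 2:6, 2:6] = 1  # vessels only in the first octant
    r = region_existence_labels(lab, (2, 2, 2))
    assert r.tolist() == [[1, 0, 0, 0, 0, 0, 0, 0]]
    assert not region_existence_labels(np.zeros((8, 8, 8), int)).any()


def test_existence_octa_hand_sum_and_zero_logits():
    q = rng.normal(size=(2, 8))
    r = rng.integers(0, 2, size=(2, 8))
    sig = 1 / (1 + np.exp(-q))
    expected = -(r * np.log(sig) + (1 - r) * np.log(1 - sig)).mean()
    assert existence_loss_octa(q, r).item() == pytest.approx(expected, rel=1e-5)
    assert existence_loss_octa(np.zeros((1, 8)), np.zeros((1, 8), int)).item() == \
        pytest.approx(np.log(2), abs=1e-6)


# -- connectivity (multi-class) ---------------------------------------------

def _dilate_oracle(x, kernel):
    """Exhaustive dilation (zero-padded): D[v] = max over kernel offsets o of
    X[v - o], with out-of-volume sources contributing background (0)."""
    out = np.zeros_like(x)
    c = np.array(kernel.shape) // 2
    for off in np.argwhere(kernel):
        o = off - c
        for v in np.ndindex(x.shape):
            src = np.array(v) - o
            if all(0 <= s < n for s, n in zip(src, x.shape)):
                out[v] = max(out[v], x[tuple(src)])
    return out


def test_grey_dilate_matches_exhaustive_oracle():
    x = rng.random((3, 3, 3)).astype(np.float32)
    for kernel in (np.ones((3, 3, 3), bool), (rng.random((3, 3, 3)) < 0.4)):
        if not kernel.any():
            kernel[1, 1, 1] = True
        got = grey_dilate(Tensor(x), kernel).data
        assert np.allclose(got, _dilate_oracle(x, kernel), atol=1e-6)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_literal_mode_is_identically_zero_for_origin_kernels(seed):
    """Dilate(X,K) >= X pointwise when K contains the origin, so the penalty
    over the valid-pair set vanishes for every input (regression-tested
    property of the formula as printed)."""
    r = np.random.default_rng(seed)
    probs = r.dirichlet(np.ones(4), size=(1, 3, 3, 3)).transpose(0, 4, 1, 2, 3)
    kernel = r.random((3, 3, 3)) < 0.5
    kernel[1, 1, 1] = True  # origin included
    graph = AdjacencyGraph({(1, 2), (2, 3)}, n_classes=4, mode="literal")
    assert connectivity_loss_mra(probs, graph, kernel).item() == 0.0


def test_complement_mode_disjoint_maps_give_zero():
    P = np.zeros((1, 3, 4, 4, 4), np.float32)
    P[0, 1, :2] = 1.0
    P[0, 2, 2:] = 1.0  # spatially disjoint classes -> product is 0
    graph = AdjacencyGraph({(1, 2)}, n_classes=3, mode="complement")
    assert connectivity_loss_mra(P, graph).item() == 0.0


def test_complement_mode_matches_brute_force_dilation_oracle():
    probs = rng.dirichlet(np.ones(4), size=(1, 3, 3, 3)).transpose(0, 4, 1, 2, 3)
    kernel = np.zeros((3, 3, 3), bool)
    kernel[1, 1, 2] = True  # 1-voxel kernel, origin NOT included
    graph = AdjacencyGraph({(1, 2)}, n_classes=4, mode="complement")
    got = connectivity_loss_mra(probs, graph, kernel).item()
    expected = 0.0
    for a, b in [(1, 3), (2, 3)]:  # complement of {(1,2)} over classes 1..3
        x = probs[0, a] * probs[0, b]
        expected += np.maximum(0.0, x - _dilate_oracle(x, kernel)).sum()
    assert got == pytest.approx(expected, rel=1e-5)
    with pytest.raises(ValueError, match="kernel"):
        connectivity_loss_mra(probs, graph, np.zeros((3, 3, 3), bool))


def test_adjacency_graph_validation():
    with pytest.raises(ValueError, match="self-pairs"):
        AdjacencyGraph({(1, 1)}, n_classes=3)
    with pytest.raises(ValueError):
        AdjacencyGraph({(0, 1)}, n_classes=3)
    g = AdjacencyGraph({(1, 2)}, n_classes=4)
    assert g.active_pairs() == [(1, 3), (2, 3)]


# -- soft skeleton & clDice loss --------------------------------------------

def test_soft_skeleton_keeps_one_voxel_line():
    vol = np.zeros((5, 5, 24), np.float32)
    vol[2, 2, 2:22] = 1.0  # 1x1x20 line embedded in background
    out = soft_skeletonize(Tensor(vol), iterations=5).data
    assert np.array_equal(out, vol)


def test_soft_skeleton_dominance_and_errors():
    x = rng.random((6, 6, 6)).astype(np.float32)
    out = soft_skeletonize(Tensor(x), iterations=3).data
    assert (out <= x + 1e-6).all()
    assert not soft_skeletonize(Tensor(np.zeros((4, 4, 4))), 2).data.any()
    with pytest.raises(ValueError):
        soft_skeletonize(Tensor(x), 0)


def test_cldice_loss_perfect_and_disjoint():
    t = tube_mask((16, 16, 16), radius=1.5).astype(np.float32)
    assert cl_dice_loss(t, t).item() == pytest.approx(0.0, abs=1e-4)
    s = np.roll(t, 6, axis=1)
    assert cl_dice_loss(s, t).item() == pytest.approx(1.0, abs=1e-4)


def test_cldice_loss_gap_sensitivity_exceeds_dice_gap():
    """Cutting a thin branch raises the clDice loss by strictly more than it
    raises a soft Dice loss on the same pair."""
    gt = tube_mask((20, 20, 20), axis=0, radius=2.5, lo=2).astype(np.float32)
    gt[10, 10, 2:18] = 1.0
    pred = gt.copy()
    pred[10, 10, 10:13] = 0.0

    def soft_dice_loss(p, g):
        return 1.0 - 2 * (p * g).sum() / (p.sum() + g.sum())

    cl_gap = cl_dice_loss(pred, gt).item() - cl_dice_loss(gt, gt).item()
    dice_gap = soft_dice_loss(pred, gt) - soft_dice_loss(gt, gt)
    assert cl_gap > dice_gap > 0


# -- total ------------------------------------------------------------------

def test_total_loss_published_weights():
    rep = total_loss(1.0, 1.0, 1.0)
    assert rep.total == pytest.approx(5.7)
    assert total_loss(1.0, 2.0, 3.0, LossWeights(0, 0, 0)).total == 0.0
    a = total_loss(0.3, 0.5, 0.7)
    b = total_loss(0.6, 1.0, 1.4)
    assert b.total == pytest.approx(2 * a.total)
    with pytest.raises(ValueError):
        total_loss(1, 1, 1, LossWeights(-1, 0.7, 4))
    with pytest.raises(ValueError):
        total_loss(np.inf, 0, 0)


# -- shared properties -------------------------------------------------------

def test_losses_are_batch_permutation_equivariant():
    logits = rng.normal(size=(3, 2, 4, 4, 4))
    labels = rng.integers(0, 2, size=(3, 4, 4, 4))
    labels[:, 0, 0, 0] = 1
    perm = [2, 0, 1]
    assert pixel_loss(logits, labels).item() == pytest.approx(
        pixel_loss(logits[perm], labels[perm]).item(), rel=1e-6)
    g = rng.normal(size=(3, 4))
    e = rng.integers(0, 2, size=(3, 4))
    assert existence_loss_mra(g, e).item() == pytest.approx(
        existence_loss_mra(g[perm], e[perm]).item(), rel=1e-6)


def test_losses_are_differentiable_with_finite_gradients():
    logits = Tensor(rng.normal(size=(1, 3, 4, 4, 4)), requires_grad=True)
    labels = rng.integers(0, 3, size=(1, 4, 4, 4))
    labels[0, 0, 0, 0] = 1
    pixel_loss(logits, labels).backward()
    assert logits.grad is not None and np.isfinite(logits.grad).all()

    probs = Tensor(rng.random((1, 4, 4, 4, 4)).astype(np.float32), requires_grad=True)
    graph = AdjacencyGraph({(1, 2)}, n_classes=4, mode="complement")
    connectivity_loss_mra(probs, graph).backward()
    assert probs.grad is not None and np.isfinite(probs.grad).all()

    p = Tensor(rng.random((8, 8, 8)).astype(np.float32), requires_grad=True)
    cl_dice_loss(p, tube_mask((8, 8, 8), radius=1.0, lo=1)).backward()
    assert p.grad is not None and np.isfinite(p.grad).all()
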