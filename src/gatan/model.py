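"""The segmentation network: a variable-window hybrid CNN–transformer encoder
with efficient multi-scale attention (EMA), multi-scale graph aggregation
(MSGA) over the encoder pyramid, a symmetric upsampling decoder, and voxel +
existence heads.

Architecture outline (channels-first, (B, C, D, H, W)):

  stem: strided 3³ conv, /2 ──► stage 0 (attention blocks [+EMA]) ──► /2 ──►
  stage 1 ... ──► MSGA-enriched skips ──► decoder (nearest ×2 + conv merges)
  ──► ×2 to input resolution ──► 1×1×1 head → C-class voxel logits.

Every attention block splits its channels into four groups: one attends in
local cubic windows, the other three in anisotropic stripe windows that span
the full depth, height or width axis respectively. Adjacent blocks alternate
between regular and shifted window partitioning (cyclic half-window
displacement plus an attention mask that forbids interactions between tokens
originating from different pre-shift windows).

The existence head is not a separate branch: per-class existence logits are
the global average pool of the class's voxel logit map (multi-class task), or
averages over a fixed grid of subvolumes (binary task).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate
from .losses import region_slices
from .nn import MLP, Conv3d, LayerNorm, Linear, Module

__all__ = ["ModelConfig", "WindowSpec", "SegmentationOutput", "partition_windows",
           "merge_windows", "window_mask", "VariableWindowAttention", "EMABlock",
           "Grapher", "MSGA", "GATAN", "build_check", "upsample2"]


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Fully determines the network. Defaults are desk-scale (CPU-trainable)."""

    n_classes: int = 2
    patch_shape: tuple = (32, 32, 32)
    channels: tuple = (8, 16)           # per stage, each divisible by 4
    depths: tuple = (2, 2)              # attention blocks per stage
    cubic_window: tuple = (4, 4)        # cubic window edge per stage
    stripe_thickness: tuple = (4, 4)    # bounded dims of stripe windows
    heads: tuple = (1, 1)               # attention heads per channel group
    graph_k: int = 9                    # feature-space k-NN for the grapher
    use_ema: bool = True
    use_msga: bool = True
    use_coords: bool = True     # append normalized global-coordinate channels
    coord_freqs: int = 2        # extra sin/cos coordinate harmonics per axis
    head_coord_freqs: int = 8   # high-freq harmonics fed straight to the head
    stripe_token_cap: int = 128         # max tokens along an unbounded axis
    task: str = "octa"                  # 'octa' (binary) or 'cow' (multi-class)
    region_grid: tuple = (2, 2, 2)      # R-cell partition for binary existence

    @property
    def n_stages(self) -> int:
        return len(self.channels)

    def stage_shape(self, i: int) -> tuple:
        return tuple(s // 2 ** (i + 1) for s in self.patch_shape)

    def validate(self):
        if self.task not in ("octa", "cow"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        n = self.n_stages
        if not (len(self.depths) == len(self.cubic_window)
                == len(self.stripe_thickness) == len(self.heads) == n):
            raise ConfigError("per-stage tuples must share one length")
        if self.graph_k < 1:
            raise ConfigError("graph_k must be >= 1")
        for i, c in enumerate(self.channels):
            if c % 4:
                raise ConfigError(f"stage {i}: channels ({c}) must be divisible by 4 "
                                  "(four window groups)")
            if (c // 4) % self.heads[i]:
                raise ConfigError(f"stage {i}: group width {c // 4} not divisible by "
                                  f"{self.heads[i]} heads")
        for i in range(n):
            dims = self.stage_shape(i)
            if any(d < 1 for d in dims):
                raise ConfigError(f"patch {self.patch_shape} too small for stage {i}")
            w = self.cubic_window[i]
            t = self.stripe_thickness[i]
            for d in dims:
                if d % w:
                    raise ConfigError(f"stage {i}: dim {d} not divisible by cubic "
                                      f"window {w}")
                if d % t:
                    raise ConfigError(f"stage {i}: dim {d} not divisible by stripe "
                                      f"thickness {t}")
                if d > self.stripe_token_cap:
                    raise ConfigError(
                        f"stage {i}: axis of {d} tokens exceeds the stripe token cap "
                        f"({self.stripe_token_cap}); use a smaller stage resolution")
            if i < n - 1 and any(d % 2 for d in dims):
                raise ConfigError(f"stage {i} dims {dims} not divisible by 2")
            if self.graph_k >= int(np.prod(dims)):
                raise ConfigError(f"graph_k={self.graph_k} must be smaller than the "
                                  f"{int(np.prod(dims))} voxels of stage {i}")
        for s, g in zip(self.patch_shape, self.region_grid):
            if self.task == "octa" and (g < 1 or s % g):
                raise ConfigError("region_grid must evenly partition the patch")
        return self


@dataclass(frozen=True)
class WindowSpec:
    """3D window geometry; -1 marks an axis spanned entirely (stripe)."""

    shape: tuple
    shifted: bool = False

    def __post_init__(self):
        if sum(1 for s in self.shape if s == -1) > 1:
            raise ConfigError("at most one unbounded axis per window")


@dataclass
class SegmentationOutput:
    voxel_logits: Tensor          # (B, C, D, H, W)
    existence_logits: Tensor      # (B, C-1) multi-class / (B, R) binary
    task: str


# ---------------------------------------------------------------------------
# window partitioning
# ---------------------------------------------------------------------------

_MASK_CACHE: dict = {}


def _resolve(spec: WindowSpec, dims):
    w = tuple(d if s == -1 else int(s) for s, d in zip(spec.shape, dims))
    for d, wi in zip(dims, w):
        if d % wi:
            raise ConfigError(f"spatial dims {dims} not divisible by window {w}")
    shifts = tuple(wi // 2 if (spec.shifted and s != -1 and wi < d) else 0
                   for s, wi, d in zip(spec.shape, w, dims))
    return w, shifts


def window_mask(dims, spec: WindowSpec) -> np.ndarray | None:
    """(nW, T, T) additive mask: -1e9 between tokens from different pre-shift
    windows, 0 otherwise. None when unshifted (no invalid pairs)."""
    w, shifts = _resolve(spec, dims)
    if not any(shifts):
        return None
    key = (dims, w, shifts)
    if key not in _MASK_CACHE:
        nd, nh, nw = (d // wi for d, wi in zip(dims, w))
        d, h, ww = np.meshgrid(*[np.arange(x) for x in dims], indexing="ij")
        ids = (d // w[0]) * nh * nw + (h // w[1]) * nw + (ww // w[2])
        ids = np.roll(ids, tuple(-s for s in shifts), axis=(0, 1, 2))
        ids = (ids.reshape(nd, w[0], nh, w[1], nw, w[2])
                  .transpose(0, 2, 4, 1, 3, 5)
                  .reshape(nd * nh * nw, w[0] * w[1] * w[2]))
        mask = np.where(ids[:, :, None] == ids[:, None, :], 0.0, -1e9)
        _MASK_CACHE[key] = mask.astype(np.float32)
    return _MASK_CACHE[key]


def partition_windows(x, spec: WindowSpec):
    """(B, D, H, W, C) -> ((B, nW, T, C) window batch, mask, merge metadata)."""
    x = as_tensor(x)
    B, D, H, W, C = x.shape
    dims = (D, H, W)
    w, shifts = _resolve(spec, dims)
    if any(shifts):
        x = x.roll(tuple(-s for s in shifts), axis=(1, 2, 3))
    nd, nh, nw = (d // wi for d, wi in zip(dims, w))
    xw = (x.reshape(B, nd, w[0], nh, w[1], nw, w[2], C)
           .transpose(0, 1, 3, 5, 2, 4, 6, 7)
           .reshape(B, nd * nh * nw, w[0] * w[1] * w[2], C))
    meta = (B, dims, w, shifts, C)
    return xw, window_mask(dims, spec), meta


def merge_windows(xw, meta) -> Tensor:
    """Exact inverse of :func:`partition_windows`."""
    B, dims, w, shifts, C = meta
    nd, nh, nw = (d // wi for d, wi in zip(dims, w))
    x = (as_tensor(xw).reshape(B, nd, nh, nw, w[0], w[1], w[2], C)
         .transpose(0, 1, 4, 2, 5, 3, 6, 7)
         .reshape(B, dims[0], dims[1], dims[2], C))
    if any(shifts):
        x = x.roll(shifts, axis=(1, 2, 3))
    return x


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

class VariableWindowAttention(Module):
    """One transformer block with four per-channel-group window geometries.

    A single shared QKV projection feeds all groups; group 0 attends in cubic
    windows, groups 1–3 in stripe windows spanning H, W and D respectively.
    Output: residual + fused concat, then a feed-forward residual.
    """

    def __init__(self, dim: int, heads: int, cubic: int, stripe: int,
                 rng: np.random.Generator):
        if dim % 4:
            raise ConfigError("channels must be divisible by 4")
        self.dim, self.heads = dim, heads
        self.specs_regular = self._specs(cubic, stripe, shifted=False)
        self.specs_shifted = self._specs(cubic, stripe, shifted=True)
        self.norm1 = LayerNorm(dim)
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, 2 * dim, rng)

    @staticmethod
    def _specs(cubic, stripe, shifted):
        return (
            WindowSpec((cubic, cubic, cubic), shifted),
            WindowSpec((stripe, -1, stripe), shifted),   # spans full H
            WindowSpec((stripe, stripe, -1), shifted),   # spans full W
            WindowSpec((-1, stripe, stripe), shifted),   # spans full D
        )

    def _attend(self, q, k, v, spec: WindowSpec):
        """Windowed multi-head attention for one channel group (channels-last)."""
        qw, mask, meta = partition_windows(q, spec)
        kw, _, _ = partition_windows(k, spec)
        vw, _, _ = partition_windows(v, spec)
        B, nW, T, gd = qw.shape
        h = self.heads
        hd = gd // h

        def split_heads(t):
            return t.reshape(B, nW, T, h, hd).transpose(0, 1, 3, 2, 4)

        qh, kh, vh = split_heads(qw), split_heads(kw), split_heads(vw)
        attn = qh @ kh.transpose(0, 1, 2, 4, 3) * (hd ** -0.5)
        if mask is not None:
            attn = attn + Tensor(mask[None, :, None])
        out = attn.softmax(axis=-1) @ vh
        out = out.transpose(0, 1, 3, 2, 4).reshape(B, nW, T, gd)
        return merge_windows(out, meta)

    def forward(self, x: Tensor, shifted: bool = False) -> Tensor:
        xt = x.transpose(0, 2, 3, 4, 1)  # channels-last tokens
        hm = self.norm1(xt)
        qkv = self.qkv(hm)
        C = self.dim
        q, k, v = qkv[..., :C], qkv[..., C:2 * C], qkv[..., 2 * C:]
        gd = C // 4
        specs = self.specs_shifted if shifted else self.specs_regular
        outs = []
        for g, spec in enumerate(specs):
            sl = slice(g * gd, (g + 1) * gd)
            outs.append(self._attend(q[..., sl], k[..., sl], v[..., sl], spec))
        xt = xt + self.proj(concatenate(outs, axis=-1))
        xt = xt + self.mlp(self.norm2(xt))
        return xt.transpose(0, 4, 1, 2, 3)


# ---------------------------------------------------------------------------
# EMA block
# ---------------------------------------------------------------------------

class EMABlock(Module):
    """Efficient multi-scale attention refinement.

    Coordinate attention: each axis is average-pooled to a per-axis channel
    descriptor, mixed through a shared bottleneck (1×1×1 convolutions realized
    as channel-wise linear maps) and turned into per-axis sigmoid gates that
    reweight the feature (F_ca). A parallel 3³ convolution branch (F_c) widens
    the local receptive field. Global average statistics of both branches are
    summed and applied as a channel reweighting of the input.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        r = max(dim // 4, 4)
        self.fc1 = Linear(dim, r, rng)
        self.fc_d = Linear(r, dim, rng)
        self.fc_h = Linear(r, dim, rng)
        self.fc_w = Linear(r, dim, rng)
        self.conv3 = Conv3d(dim, dim, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.shape
        pd = x.mean(axis=(3, 4)).transpose(0, 2, 1)   # (B, D, C)
        ph = x.mean(axis=(2, 4)).transpose(0, 2, 1)   # (B, H, C)
        pw = x.mean(axis=(2, 3)).transpose(0, 2, 1)   # (B, W, C)
        h = self.fc1(concatenate([pd, ph, pw], axis=1)).relu()
        gd = self.fc_d(h[:, :D]).sigmoid().transpose(0, 2, 1).reshape(B, C, D, 1, 1)
        gh = self.fc_h(h[:, D:D + H]).sigmoid().transpose(0, 2, 1).reshape(B, C, 1, H, 1)
        gw = self.fc_w(h[:, D + H:]).sigmoid().transpose(0, 2, 1).reshape(B, C, 1, 1, W)
        f_ca = x * gd * gh * gw
        f_c = self.conv3(x)
        stats = f_ca.mean(axis=(2, 3, 4)) + f_c.mean(axis=(2, 3, 4))  # cross-branch sum
        gate = stats.sigmoid().reshape(B, C, 1, 1, 1)
        return x * gate


# ---------------------------------------------------------------------------
# graph aggregation
# ---------------------------------------------------------------------------

class Grapher(Module):
    """Max-relative graph convolution over voxel nodes.

    Each voxel links to its ``k`` nearest neighbors in feature space; the
    aggregated message is the element-wise maximum of neighbor-minus-center
    differences, combined with the center by a linear update and a residual.
    """

    def __init__(self, dim: int, k: int, rng: np.random.Generator):
        if k < 1:
            raise ConfigError("graph_k must be >= 1")
        self.k = k
        self.fc = Linear(2 * dim, dim, rng)

    @staticmethod
    def knn_indices(feats: np.ndarray, k: int) -> np.ndarray:
        """(B, N, C) features -> (B, N, k) nearest-neighbor indices
        (Euclidean, self excluded)."""
        B, N, _ = feats.shape
        if k >= N:
            raise ConfigError(f"graph_k={k} needs more than {N} nodes")
        idx = np.empty((B, N, k), dtype=np.intp)
        for b in range(B):  # in-place distance assembly, one (N, N) buffer
            f = feats[b]
            sq = np.einsum("nc,nc->n", f, f)
            d2 = f @ f.T
            d2 *= -2.0
            d2 += sq[:, None]
            d2 += sq[None, :]
            np.fill_diagonal(d2, np.inf)  # exclude self-loops
            # neighbor order is irrelevant to the max aggregation
            idx[b] = np.argpartition(d2, k - 1, axis=-1)[:, :k]
        return idx

    def forward(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.shape
        N = D * H * W
        nodes = x.reshape(B, C, N).transpose(0, 2, 1)       # (B, N, C)
        idx = self.knn_indices(nodes.data, self.k)           # detached selection
        bi = np.arange(B)[:, None, None]
        nbrs = nodes[bi, idx]                                # (B, N, k, C)
        rel = nbrs - nodes.reshape(B, N, 1, C)
        msg = rel.max(axis=2)                                # max-relative aggregation
        upd = self.fc(concatenate([nodes, msg], axis=-1))
        out = nodes + upd
        return out.transpose(0, 2, 1).reshape(B, C, D, H, W)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor ×2 upsampling of the three trailing spatial axes."""
    B, C, D, H, W = x.shape
    x = concatenate([x.reshape(B, C, D, 1, H, W)] * 2, axis=3).reshape(B, C, 2 * D, H, W)
    x = concatenate([x.reshape(B, C, 2 * D, H, 1, W)] * 2, axis=4).reshape(B, C, 2 * D, 2 * H, W)
    x = concatenate([x.reshape(B, C, 2 * D, 2 * H, W, 1)] * 2, axis=5).reshape(B, C, 2 * D, 2 * H, 2 * W)
    return x


class MSGA(Module):
    """Multi-scale graph aggregation across the encoder pyramid.

    Level i receives its own grapher output concatenated with every deeper
    grapher output (1×1×1 channel alignment, nearest resize to level-i
    resolution), refined by a 3³ convolution and added residually to the
    plain skip feature.
    """

    def __init__(self, channels, graph_k: int, rng: np.random.Generator):
        n = len(channels)
        self.graphers = [Grapher(c, graph_k, rng) for c in channels]
        self.aligns = [[Conv3d(channels[j], channels[i], 1, rng)
                        for j in range(i + 1, n)] for i in range(n)]
        self.refines = [Conv3d(channels[i] * (n - i), channels[i], 3, rng, padding=1)
                        for i in range(n)]

    def forward(self, pyramid) -> list:
        if len({f.shape[0] for f in pyramid}) != 1:
            raise ValueError("pyramid levels disagree on batch size")
        n = len(pyramid)
        graphs = [g(f) for g, f in zip(self.graphers, pyramid)]
        out = []
        for i in range(n):
            parts = [graphs[i]]
            for jj, j in enumerate(range(i + 1, n)):
                g = self.aligns[i][jj](graphs[j])
                for _ in range(j - i):
                    g = upsample2(g)
                parts.append(g)
            fused = concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
            out.append(pyramid[i] + self.refines[i](fused))
        return out


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class GATAN(Module):
    """Variable-window hybrid backbone + EMA + MSGA + segmentation heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        n = config.n_stages

        c_in = 1 + (3 * (1 + 2 * config.coord_freqs) if config.use_coords else 0)
        self.stem = Conv3d(c_in, ch[0], 3, rng, stride=2, padding=1)
        # full-resolution CNN path: lets the decoder recover 1-voxel detail
        # that the strided stem discards
        self.fullres = Conv3d(c_in, max(ch), 3, rng, padding=1)
        self.stages = [
            [VariableWindowAttention(ch[i], config.heads[i], config.cubic_window[i],
                                     config.stripe_thickness[i], rng)
             for _ in range(config.depths[i])]
            for i in range(n)
        ]
        self.emas = [EMABlock(ch[i], rng) for i in range(n)]
        self.downs = [Conv3d(ch[i], ch[i + 1], 2, rng, stride=2) for i in range(n - 1)]
        self.msga = MSGA(ch, config.graph_k, rng)
        self.up_projs = [Conv3d(ch[i + 1], ch[i], 1, rng) for i in range(n - 1)]
        self.merges = [Conv3d(2 * ch[i], ch[i], 3, rng, padding=1) for i in range(n - 1)]
        head_w = max(ch)  # widest stage width for the pre-head features
        self.final_conv = Conv3d(ch[0] + head_w, head_w, 3, rng, padding=1)
        head_in = head_w
        if config.use_coords and config.head_coord_freqs:
            head_in += 6 * config.head_coord_freqs
        self.head = Conv3d(head_in, config.n_classes, 1, rng)
        # near-zero head: initial logits ~0 (uniform softmax), so early
        # gradients are well-scaled instead of undoing confident noise
        self.head.weight.data *= 0.01

    def forward(self, x, origin=None, full_shape=None) -> SegmentationOutput:
        """Segment one batch of patches.

        ``origin`` (per-batch or shared (3,) voxel corner) and ``full_shape``
        locate the patch inside its source volume so the coordinate channels
        carry *global* position — left/right arterial classes are not
        separable from appearance alone.
        """
        x = as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 4:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        if tuple(x.shape[2:]) != tuple(self.config.patch_shape):
            raise ValueError(f"input spatial shape {x.shape[2:]} does not match "
                             f"configured patch {self.config.patch_shape}")
        cfg = self.config
        head_pos = None
        if cfg.use_coords:
            x = concatenate(
                [x, Tensor(self._coord_channels(x.shape, origin, full_shape))],
                axis=1)
            if cfg.head_coord_freqs:
                head_pos = Tensor(self._coord_channels(
                    (x.shape[0], None) + tuple(x.shape[2:]), origin, full_shape,
                    freqs=cfg.head_coord_freqs, include_raw=False))
        f = self.stem(x)
        feats = []
        for i, blocks in enumerate(self.stages):
            for bi, blk in enumerate(blocks):
                f = blk(f, shifted=bool(bi % 2))
            if cfg.use_ema:
                f = self.emas[i](f)
            feats.append(f)
            if i < cfg.n_stages - 1:
                f = self.downs[i](f)
        skips = self.msga(feats) if cfg.use_msga else feats
        d = skips[-1]
        for i in range(cfg.n_stages - 2, -1, -1):
            d = self.up_projs[i](upsample2(d))
            d = self.merges[i](concatenate([d, skips[i]], axis=1)).relu()
        full = self.fullres(x).relu()
        d = self.final_conv(concatenate([upsample2(d), full], axis=1)).relu()
        if head_pos is not None:
            d = concatenate([d, head_pos], axis=1)
        logits = self.head(d)
        existence = self._existence(logits)
        return SegmentationOutput(logits, existence, cfg.task)

    def _coord_channels(self, shape, origin, full_shape, freqs=None,
                        include_raw=True) -> np.ndarray:
        B = shape[0]
        patch = shape[2:]
        full = np.broadcast_to(
            np.asarray(full_shape if full_shape is not None else patch, float),
            (B, 3))
        org = np.zeros((B, 3)) if origin is None else \
            np.broadcast_to(np.asarray(origin, float), (B, 3))
        F = self.config.coord_freqs if freqs is None else freqs
        n_ch = 3 * ((1 if include_raw else 0) + 2 * F)
        out = np.empty((B, n_ch) + tuple(patch), dtype=np.float32)
        for b in range(B):
            axes = [(org[b, i] + np.arange(patch[i])) / max(full[b, i] - 1.0, 1.0)
                    for i in range(3)]
            grids = np.stack(np.meshgrid(*axes, indexing="ij"))
            feats = [grids] if include_raw else []
            for f in range(1, F + 1):  # Fourier harmonics ease region carving
                feats.append(np.sin(np.pi * f * grids))
                feats.append(np.cos(np.pi * f * grids))
            out[b] = np.concatenate(feats, axis=0)
        return out

    def _existence(self, logits: Tensor) -> Tensor:
        if self.config.task == "cow":
            B, C = logits.shape[:2]
            nvox = int(np.prod(logits.shape[2:]))
            return logits[:, 1:].reshape(B, C - 1, nvox).mean(axis=-1)
        # binary task: region-wise occupancy logits over the configured grid
        parts = []
        for sl in region_slices(logits.shape[2:], self.config.region_grid):
            region = logits[(slice(None), slice(1, 2)) + sl]
            parts.append(region.mean(axis=(2, 3, 4)))
        return concatenate(parts, axis=1)


def build_check(config: ModelConfig, seed: int = 0) -> GATAN:
    """Validate the configuration and prove end-to-end shape consistency with
    one dummy forward pass (no training)."""
    model = GATAN(config, seed=seed)
    out = model(np.zeros((1, 1) + tuple(config.patch_shape), dtype=np.float32))
    expect = (1, config.n_classes) + tuple(config.patch_shape)
    if tuple(out.voxel_logits.shape) != expect:
        raise ConfigError(f"voxel logits {out.voxel_logits.shape} != {expect}")
    return model
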