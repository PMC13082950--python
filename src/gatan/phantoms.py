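"""Synthetic 3D vascular phantoms.

Real OCTA microvascular volumes and multi-class Circle-of-Willis (CoW) MRA
annotations are not redistributable, so every downstream component of this
package is exercised on phantoms that reproduce the *statistical* structure
the method targets:

* multi-scale tubular trees with monotone radius taper (extreme scale
  imbalance between trunks and leaves);
* a parametric 13-class CoW with topological variants (missing communicating
  arteries, accessory A2 segment);
* modality-specific corruption — speckle plus slice-wise flow dropouts for
  OCTA, smooth multiplicative bias fields plus Gaussian noise for MRA.

All generators are pure functions of ``(parameters, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "COW_CLASS_NAMES", "COW_N_CLASSES", "CANONICAL_COW_EDGES", "COW_VARIANTS",
    "VesselTree", "PhantomVolume", "generate_tree", "rasterize",
    "make_cow_phantom", "make_octa_phantom", "apply_octa_noise",
    "apply_mra_noise", "save_phantom", "load_phantom",
]

# 13-class CoW label space; index 0 is background.
COW_CLASS_NAMES = (
    "BA", "PCA-L", "PCA-R", "MCA-L", "MCA-R", "ICA-L", "ICA-R",
    "Pcomm-L", "Pcomm-R", "Acomm", "ACA-L", "ACA-R", "3rd-A2",
)
COW_N_CLASSES = 14  # background + 13 arteries
_IDX = {n: i + 1 for i, n in enumerate(COW_CLASS_NAMES)}

#: Canonical CoW wiring (editable; the anatomically valid connection pairs).
CANONICAL_COW_EDGES = tuple(sorted(
    tuple(sorted((_IDX[a], _IDX[b]))) for a, b in [
        ("BA", "PCA-L"), ("BA", "PCA-R"),
        ("PCA-L", "Pcomm-L"), ("PCA-R", "Pcomm-R"),
        ("Pcomm-L", "ICA-L"), ("Pcomm-R", "ICA-R"),
        ("ICA-L", "MCA-L"), ("ICA-R", "MCA-R"),
        ("ICA-L", "ACA-L"), ("ICA-R", "ACA-R"),
        ("ACA-L", "Acomm"), ("ACA-R", "Acomm"),
        ("Acomm", "3rd-A2"),
    ]
))

COW_VARIANTS = ("complete", "missing_acomm", "missing_pcomm_l",
                "missing_pcomm_r", "extra_3rd_a2")


@dataclass
class VesselTree:
    """A vascular tree as a node/edge skeleton in continuous voxel coordinates.

    ``nodes`` are 3D points, ``edges`` parent→child index pairs, ``radii``
    per-node tube radii (voxels, strictly positive, non-increasing from root
    to leaf), ``edge_class`` the foreground label of each edge.
    """

    nodes: np.ndarray            # (N, 3) float
    edges: list                  # [(parent, child), ...]
    radii: np.ndarray            # (N,) float > 0
    edge_class: list             # len(edges), ints >= 1

    def validate(self):
        assert len(self.edges) == len(self.edge_class)
        assert np.all(self.radii > 0), "radii must be strictly positive"
        for p, c in self.edges:
            assert self.radii[c] <= self.radii[p] + 1e-9, "taper must be monotone"
        # acyclic + connected: every non-root node has exactly one parent
        children = [c for _, c in self.edges]
        assert len(set(children)) == len(children), "node with two parents"
        assert len(self.edges) == len(self.nodes) - 1, "tree must be connected/acyclic"


@dataclass
class PhantomVolume:
    """A synthetic labeled case: intensity + labels + topology ground truth."""

    intensity: np.ndarray        # float32 in [0, 1], shape (D, H, W)
    labels: np.ndarray           # int16 in [0, C-1]
    spacing: tuple               # mm per axis
    existence: np.ndarray        # uint8, length C-1 (per foreground class)
    adjacency: set               # unordered class-index pairs, e.g. {(1, 2), ...}
    variant_tag: str
    seed: int
    task: str = "cow"

    @property
    def n_classes(self) -> int:
        return len(self.existence) + 1

    def validate(self):
        assert self.intensity.shape == self.labels.shape
        present = np.zeros(self.n_classes - 1, dtype=np.uint8)
        for c in np.unique(self.labels):
            if c > 0:
                present[c - 1] = 1
        assert np.array_equal(present, self.existence), \
            "existence vector inconsistent with labels"
        for a, b in self.adjacency:
            assert a != b and 1 <= a < self.n_classes and 1 <= b < self.n_classes


# ---------------------------------------------------------------------------
# tree generation & rasterization
# ---------------------------------------------------------------------------

#: Per-level taper jitter: effective taper = 1 - (1-taper)*U(lo, hi), so a
#: taper of 1.0 stays exactly 1.0 (constant-radius tube).
TAPER_JITTER = (0.8, 1.2)


def taper_bounds(root_radius: float, taper: float, n_branch_levels: int):
    """Closed-form [lo, hi] bounds on leaf radii implied by the jitter config."""
    lo = root_radius * max(1.0 - (1.0 - taper) * TAPER_JITTER[1], 0.05) ** n_branch_levels
    hi = root_radius * (1.0 - (1.0 - taper) * TAPER_JITTER[0]) ** n_branch_levels
    return lo, hi


def _unit(v):
    return v / np.linalg.norm(v)


def generate_tree(seed: int, n_branch_levels: int, root_radius: float, taper: float,
                  domain_shape, segment_class: int = 1) -> VesselTree:
    """Grow a random binary-branching tree inside ``domain_shape``.

    Level 1 is a single unbranched segment from the root; each further level
    doubles the branch count. Radii shrink by ``taper`` (jittered, see
    :data:`TAPER_JITTER`) at each level and never increase.
    """
    if n_branch_levels < 1:
        raise ValueError("n_branch_levels must be >= 1")
    if root_radius < 0.5:
        raise ValueError("root_radius must be >= 0.5 voxels")
    if not 0.0 < taper <= 1.0:
        raise ValueError("taper must lie in (0, 1]")
    shape = np.asarray(domain_shape, dtype=float)
    margin = root_radius + 1.0
    if np.any(shape - 2 * margin <= 2.0):
        raise ValueError(
            f"domain {tuple(int(s) for s in shape)} too small to contain a tube of "
            f"root radius {root_radius}; need every axis > {2 * margin + 2:.1f} voxels"
        )
    rng = np.random.default_rng(seed)

    lo, hi = margin, shape - margin

    def clamp(p):
        return np.minimum(np.maximum(p, lo), hi)

    root = clamp(shape * (0.3 + 0.1 * rng.random(3)))
    direction = _unit(rng.normal(size=3))
    seg_len = float(min(shape)) * 0.45

    nodes = [root]
    radii = [float(root_radius)]
    edges: list = []
    edge_class: list = []
    frontier = [(0, direction, seg_len)]
    for level in range(1, n_branch_levels + 1):
        nxt = []
        n_children = 1 if level == 1 else 2
        for parent, pdir, plen in frontier:
            for _ in range(n_children):
                u = rng.uniform(*TAPER_JITTER)
                eff = float(np.clip(1.0 - (1.0 - taper) * u, 0.05, 1.0))
                r = radii[parent] * eff
                d = _unit(pdir + (0.0 if level == 1 else 0.7) * rng.normal(size=3))
                end = clamp(nodes[parent] + d * plen)
                nodes.append(end)
                radii.append(r)
                child = len(nodes) - 1
                edges.append((parent, child))
                edge_class.append(int(segment_class))
                nxt.append((child, d, plen * 0.65))
        frontier = nxt
    tree = VesselTree(np.asarray(nodes), edges, np.asarray(radii), edge_class)
    tree.validate()
    return tree


def _paint_segment(labels: np.ndarray, p0, p1, radius: float, cls: int):
    """Label voxels whose centers lie within ``radius`` of segment p0-p1.

    Overlaps are resolved in favour of the smaller class index.
    """
    shape = labels.shape
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1), 0).astype(int)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1) + 1,
                    np.asarray(shape)).astype(int)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.astype(float) for g in grids], axis=-1)
    seg = p1 - p0
    seg_sq = float(seg @ seg)
    if seg_sq < 1e-12:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ seg) / seg_sq, 0.0, 1.0)
        proj = p0 + t[..., None] * seg
        dist = np.linalg.norm(pts - proj, axis=-1)
    inside = dist <= radius
    sub = labels[tuple(slice(l, h) for l, h in zip(lo, hi))]
    write = inside & ((sub == 0) | (sub > cls))
    sub[write] = cls


def rasterize(tree: VesselTree, shape) -> np.ndarray:
    """Voxelize a tree: label = class of the covering edge (crisp, no partial
    volume); the tube radius of an edge is the radius at its parent node."""
    labels = np.zeros(tuple(int(s) for s in shape), dtype=np.int16)
    for (p, c), cls in zip(tree.edges, tree.edge_class):
        _paint_segment(labels, tree.nodes[p], tree.nodes[c], float(tree.radii[p]), cls)
    return labels


def render_intensity(labels: np.ndarray, fg_level: float = 0.85, bg_level: float = 0.08,
                     smooth_sigma: float = 0.7) -> np.ndarray:
    """Anti-aliased intensity rendering of a label volume."""
    img = np.where(labels > 0, fg_level, bg_level).astype(np.float32)
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Circle-of-Willis phantom
# ---------------------------------------------------------------------------

def _cow_polylines():
    """Stylized CoW centerlines in normalized (d, h, w) coordinates.

    d = axial, h = posterior(0) -> anterior(1), w = left(0) -> right(1).
    Radii are fractions of min(shape).
    """
    T = (0.45, 0.28, 0.50)        # basilar tip
    PL, PR = (0.50, 0.38, 0.30), (0.50, 0.38, 0.70)     # PCA tips
    IL, IR = (0.50, 0.55, 0.30), (0.50, 0.55, 0.70)     # ICA tops
    AL, AR = (0.55, 0.74, 0.44), (0.55, 0.74, 0.56)     # ACA tips
    M = (0.55, 0.74, 0.50)        # Acomm midpoint
    thick, mid, thin = 0.050, 0.040, 0.026
    return {
        "BA":      ([(0.25, 0.14, 0.50), T], thick),
        "PCA-L":   ([T, PL], mid),
        "PCA-R":   ([T, PR], mid),
        "ICA-L":   ([(0.25, 0.58, 0.28), IL], thick),
        "ICA-R":   ([(0.25, 0.58, 0.72), IR], thick),
        "Pcomm-L": ([PL, IL], thin),
        "Pcomm-R": ([PR, IR], thin),
        "MCA-L":   ([IL, (0.60, 0.60, 0.10)], mid),
        "MCA-R":   ([IR, (0.60, 0.60, 0.90)], mid),
        "ACA-L":   ([IL, AL], mid),
        "ACA-R":   ([IR, AR], mid),
        "Acomm":   ([AL, AR], thin),
        "3rd-A2":  ([M, (0.62, 0.92, 0.50)], thin),
    }


def make_cow_phantom(variant: str, seed: int, shape=(64, 64, 64),
                     spacing=(0.6, 0.6, 0.6)) -> PhantomVolume:
    """Parametric Circle-of-Willis phantom with a topological variant injected.

    The base circle carries 12 arterial segments; ``extra_3rd_a2`` adds the
    accessory A2 segment and the ``missing_*`` variants delete the named
    communicating artery entirely (its label never appears and its existence
    bit is 0). The adjacency set is the canonical wiring restricted to the
    classes present.
    """
    if variant not in COW_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; options: {COW_VARIANTS}")
    shape = tuple(int(s) for s in shape)
    if any(s < 48 for s in shape):
        raise ValueError("make_cow_phantom requires shape >= (48, 48, 48)")

    drop = {"missing_acomm": "Acomm", "missing_pcomm_l": "Pcomm-L",
            "missing_pcomm_r": "Pcomm-R"}.get(variant)
    names = [n for n in COW_CLASS_NAMES if n != drop]
    if variant != "extra_3rd_a2":
        names = [n for n in names if n != "3rd-A2"]

    rng = np.random.default_rng(seed)
    jitter = {n: rng.normal(0.0, 0.006, size=3) for n in COW_CLASS_NAMES}

    sc = np.asarray(shape, dtype=float)
    rad_scale = float(min(shape))
    labels = np.zeros(shape, dtype=np.int16)
    polys = _cow_polylines()
    # paint in class order so the smaller-class tie-break is deterministic
    for name in sorted(names, key=lambda n: _IDX[n], reverse=True):
        pts, rfrac = polys[name]
        pts = [np.asarray(p) * sc + jitter[name] * rad_scale for p in pts]
        for p0, p1 in zip(pts[:-1], pts[1:]):
            _paint_segment(labels, p0, p1, rfrac * rad_scale, _IDX[name])

    existence = np.zeros(COW_N_CLASSES - 1, dtype=np.uint8)
    for n in names:
        existence[_IDX[n] - 1] = 1
    present = set(_IDX[n] for n in names)
    adjacency = {e for e in CANONICAL_COW_EDGES if e[0] in present and e[1] in present}

    intensity = render_intensity(labels)
    pv = PhantomVolume(intensity, labels, tuple(spacing), existence, adjacency,
                       variant, int(seed), task="cow")
    pv.validate()
    return pv


# ---------------------------------------------------------------------------
# OCTA-like phantom
# ---------------------------------------------------------------------------

def make_octa_phantom(seed: int, shape=(32, 32, 32), n_trees: int = 2,
                      root_radius: float = 2.2, n_branch_levels: int = 3,
                      taper: float = 0.8, spacing=(0.012, 0.012, 0.012),
                      speckle_sigma: float = 0.0, dropout_rate: float = 0.0,
                      dropout_len: int = 3) -> PhantomVolume:
    """Layered capillary-style binary phantom (vessel vs. background).

    Several multi-scale trees are rasterized into one binary label volume;
    the intensity carries a depth-layered background profile (emulating the
    plexus banding of OCTA volumes) and optional speckle/dropout corruption.
    Labels are never touched by the corruption.
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(tuple(int(s) for s in shape), dtype=np.int16)
    for t in range(n_trees):
        tree = generate_tree(int(rng.integers(2**31)), n_branch_levels,
                             root_radius, taper, shape, segment_class=1)
        labels = np.maximum(labels, rasterize(tree, shape))

    intensity = render_intensity(labels)
    # depth-layered background banding along the first axis
    d = np.arange(shape[0], dtype=np.float32)
    bands = 0.05 * (0.5 + 0.5 * np.sin(2.0 * np.pi * d / max(shape[0] / 2.0, 1.0)))
    intensity = np.clip(intensity + bands[:, None, None], 0.0, 1.0).astype(np.float32)

    tag = "complete"
    if speckle_sigma > 0 or dropout_rate > 0:
        intensity = apply_octa_noise(intensity, speckle_sigma, dropout_rate,
                                     dropout_len, seed=int(rng.integers(2**31)))
        tag = "corrupted"

    existence = np.array([1 if (labels > 0).any() else 0], dtype=np.uint8)
    pv = PhantomVolume(intensity, labels, tuple(spacing), existence, set(),
                       tag, int(seed), task="octa")
    pv.validate()
    return pv


# ---------------------------------------------------------------------------
# modality-specific corruption
# ---------------------------------------------------------------------------

def apply_octa_noise(intensity: np.ndarray, speckle_sigma: float, dropout_rate: float,
                     dropout_len: int = 3, seed: int = 0) -> np.ndarray:
    """Multiplicative speckle + slice-wise flow-signal dropouts.

    Dropouts emulate OCTA motion/flow voids: runs of ``dropout_len``
    consecutive cross-sections (along axis 0) are attenuated. ``dropout_rate``
    is the probability that a given slice starts a dropout run.
    """
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must lie in [0, 1]")
    if speckle_sigma < 0:
        raise ValueError("speckle_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.asarray(intensity, dtype=np.float32).copy()
    if speckle_sigma > 0:
        # lognormal multiplicative speckle with unit median
        out = out * np.exp(rng.normal(0.0, speckle_sigma, size=out.shape)
                           ).astype(np.float32)
    if dropout_rate > 0:
        n = out.shape[0]
        starts = rng.random(n) < dropout_rate
        atten = rng.uniform(0.05, 0.35, size=n).astype(np.float32)
        factor = np.ones(n, dtype=np.float32)
        for i in np.flatnonzero(starts):
            factor[i:i + max(int(dropout_len), 1)] = np.minimum(
                factor[i:i + max(int(dropout_len), 1)], atten[i])
        out = out * factor[:, None, None]
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def apply_mra_noise(intensity: np.ndarray, bias_scale: float, noise_sigma: float,
                    seed: int = 0) -> np.ndarray:
    """Smooth multiplicative bias field (spatial mean 1) + additive Gaussian noise."""
    if bias_scale < 0 or noise_sigma < 0:
        raise ValueError("bias_scale and noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.asarray(intensity, dtype=np.float64).copy()
    if bias_scale > 0:
        coarse = rng.normal(size=(4, 4, 4))
        zoom = [s / 4.0 for s in out.shape]
        f = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
        field = np.exp(bias_scale * f)
        field /= field.mean()  # normalized: spatial mean exactly 1
        out = out * field
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# on-disk format: NIfTI pair + JSON sidecar
# ---------------------------------------------------------------------------

def save_phantom(pv: PhantomVolume, out_dir, stem: str) -> dict:
    """Write ``<stem>_img.nii.gz``, ``<stem>_lab.nii.gz`` and ``<stem>_meta.json``."""
    from . import volume_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": str(out_dir / f"{stem}_img.nii.gz"),
        "labels": str(out_dir / f"{stem}_lab.nii.gz"),
        "meta": str(out_dir / f"{stem}_meta.json"),
    }
    volume_io.write_array(pv.intensity, pv.spacing, paths["image"])
    volume_io.write_array(pv.labels, pv.spacing, paths["labels"])
    meta = {
        "existence": pv.existence.tolist(),
        "adjacency": sorted([list(e) for e in pv.adjacency]),
        "variant_tag": pv.variant_tag,
        "seed": pv.seed,
        "task": pv.task,
        "spacing": list(pv.spacing),
    }
    Path(paths["meta"]).write_text(json.dumps(meta, indent=2))
    return paths


def load_phantom(out_dir, stem: str) -> PhantomVolume:
    from . import volume_io

    out_dir = Path(out_dir)
    img, spacing = volume_io.read_array(out_dir / f"{stem}_img.nii.gz")
    lab, _ = volume_io.read_array(out_dir / f"{stem}_lab.nii.gz")
    meta = json.loads((out_dir / f"{stem}_meta.json").read_text())
    pv = PhantomVolume(
        img.astype(np.float32), lab.astype(np.int16), tuple(meta["spacing"]),
        np.asarray(meta["existence"], dtype=np.uint8),
        {tuple(e) for e in meta["adjacency"]},
        meta["variant_tag"], int(meta["seed"]), meta.get("task", "cow"),
    )
    pv.validate()
    return pv
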