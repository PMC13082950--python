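"""Volume I/O, intensity normalization, patch extraction and dataset splitting.

Arrays are indexed ``(D, H, W)``, 0-based; physical voxel spacing (mm/axis) is
carried separately and written into the NIfTI affine diagonal.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeRecord", "SplitPlan", "read_volume", "write_volume",
           "read_array", "write_array", "normalize_intensity",
           "extract_patches", "stratified_split"]


@dataclass
class VolumeRecord:
    """One case: an intensity volume, optional labels, spacing and metadata."""

    intensity: np.ndarray
    labels: np.ndarray | None = None
    spacing: tuple = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def validate(self):
        assert self.intensity.ndim == 3
        if self.labels is not None:
            assert self.labels.shape == self.intensity.shape
        assert all(s > 0 for s in self.spacing)

    @property
    def record_id(self) -> str:
        return self.meta.get("id", self.meta.get("source", "<anon>"))


@dataclass
class SplitPlan:
    train: list
    val: list
    test: list
    ratios: tuple = (6, 2, 2)
    stratify_key: str = "variant_tag"

    def as_dict(self):
        return {"train": self.train, "val": self.val, "test": self.test,
                "ratios": list(self.ratios), "stratify_key": self.stratify_key}

    def save(self, path):
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    @classmethod
    def load(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(d["train"], d["val"], d["test"], tuple(d["ratios"]),
                   d["stratify_key"])


def write_array(arr: np.ndarray, spacing, path) -> str:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))
    return str(path)


def read_array(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_volume(record: VolumeRecord, path) -> str:
    """Write the intensity volume (and labels alongside, if present)."""
    record.validate()
    path = str(path)
    write_array(record.intensity, record.spacing, path)
    if record.labels is not None:
        write_array(record.labels, record.spacing, _label_path(path))
    return path


def _label_path(path: str) -> str:
    for ext in (".nii.gz", ".nii"):
        if path.endswith(ext):
            return path[: -len(ext)] + "_lab" + ext
    return path + "_lab.nii.gz"


def read_volume(path, with_labels: bool = True) -> VolumeRecord:
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    intensity, spacing = read_array(path)
    labels = None
    lab = _label_path(path)
    if with_labels and Path(lab).exists():
        labels, _ = read_array(lab)
        labels = labels.astype(np.int16)
    rec = VolumeRecord(intensity.astype(np.float32), labels, spacing,
                       {"source": path, "id": Path(path).name})
    rec.validate()
    return rec


def normalize_intensity(record: VolumeRecord, mode: str = "minmax") -> VolumeRecord:
    x = record.intensity.astype(np.float32)
    if mode == "zscore":
        sd = float(x.std())
        if sd == 0:
            raise ValueError("zscore normalization undefined for a constant volume")
        x = (x - x.mean()) / sd
    elif mode == "minmax":
        lo, hi = float(x.min()), float(x.max())
        x = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return VolumeRecord(x, record.labels, record.spacing, dict(record.meta))


def _pad_to(arr, shape, value=0):
    pads = []
    for s, t in zip(arr.shape, shape):
        extra = max(t - s, 0)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode="constant", constant_values=value)
    return arr


def extract_patches(record: VolumeRecord, patch_shape, n: int,
                    fg_fraction: float = 0.0, seed: int = 0,
                    mode: str = "random", with_corners: bool = False) -> list:
    """Sample ``n`` (image, label) patches.

    At least ``fg_fraction`` of the patches are guaranteed to contain
    foreground (sampled by centering on a random foreground voxel).
    Volumes smaller than the patch are symmetrically zero-padded.
    ``mode='grid'`` instead tiles the volume on a regular sliding grid
    (``n`` is then an upper bound on the count). With ``with_corners`` each
    item is ``(image, labels, corner)`` — the patch corner in the (padded)
    volume, which positional models need.
    """
    patch_shape = tuple(int(p) for p in patch_shape)
    if fg_fraction > 0 and record.labels is None:
        raise ValueError("fg_fraction > 0 requires labels")
    img = _pad_to(record.intensity, patch_shape)
    lab = _pad_to(record.labels, patch_shape) if record.labels is not None else None
    rng = np.random.default_rng(seed)
    span = [s - p for s, p in zip(img.shape, patch_shape)]

    def cut(corner):
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_shape))
        item = (img[sl].copy(), lab[sl].copy() if lab is not None else None)
        return item + (tuple(int(c) for c in corner),) if with_corners else item

    if mode == "grid":
        corners = [
            (d, h, w)
            for d in range(0, span[0] + 1, patch_shape[0])
            for h in range(0, span[1] + 1, patch_shape[1])
            for w in range(0, span[2] + 1, patch_shape[2])
        ][:n]
        return [cut(c) for c in corners]
    if mode != "random":
        raise ValueError(f"unknown sampling mode {mode!r}")

    n_fg = int(np.ceil(fg_fraction * n))
    fg_voxels = np.argwhere(lab > 0) if (lab is not None and n_fg > 0) else None
    if n_fg > 0 and (fg_voxels is None or len(fg_voxels) == 0):
        raise ValueError("fg_fraction > 0 but the volume has no foreground")
    out = []
    for i in range(n):
        if i < n_fg:
            center = fg_voxels[rng.integers(len(fg_voxels))]
            corner = [int(np.clip(c - p // 2 + rng.integers(-2, 3), 0, sp))
                      for c, p, sp in zip(center, patch_shape, span)]
        else:
            corner = [int(rng.integers(sp + 1)) for sp in span]
        out.append(cut(corner))
    return out


def stratified_split(records, ratios=(6, 2, 2), stratify_key: str = "variant_tag",
                     seed: int = 0) -> SplitPlan:
    """Variant-stratified train/val/test partition.

    Within each stratum the realized counts follow ``ratios`` as closely as
    integer arithmetic allows (largest shares first, remainders assigned
    train-first). Membership is a pure function of the *set* of record ids
    and the seed — the input order is irrelevant.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    strata: dict = {}
    for rec in records:
        key = rec.meta.get(stratify_key, "<none>") if isinstance(rec, VolumeRecord) else rec[1]
        rid = rec.record_id if isinstance(rec, VolumeRecord) else rec[0]
        strata.setdefault(str(key), []).append(str(rid))
    total = sum(ratios)
    out = {0: [], 1: [], 2: []}
    for key in sorted(strata):
        ids = sorted(strata[key])  # canonical order -> order invariance
        rng = np.random.default_rng([seed, zlib.crc32(key.encode())])
        rng.shuffle(ids)
        n = len(ids)
        counts = [n * r // total for r in ratios]
        for i in range(n - sum(counts)):  # remainders: train first
            counts[i % 3] += 1
        lo = 0
        for part, c in enumerate(counts):
            out[part].extend(ids[lo:lo + c])
            lo += c
    return SplitPlan(sorted(out[0]), sorted(out[1]), sorted(out[2]),
                     tuple(ratios), stratify_key)
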