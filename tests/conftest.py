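import numpy as np
import pytest

from gatan.phantoms import VesselTree, make_cow_phantom, make_octa_phantom


def straight_tube_tree(p0, p1, radius, cls=1):
    nodes = np.asarray([p0, p1], dtype=float)
    return VesselTree(nodes, [(0, 1)], np.asarray([radius, radius], float), [cls])


def tube_mask(shape, axis=0, radius=1.0, lo=4, hi=None):
    """Binary straight tube along ``axis`` through the volume center."""
    shape = tuple(shape)
    hi = shape[axis] - lo if hi is None else hi
    mask = np.zeros(shape, dtype=bool)
    center = [s // 2 for s in shape]
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    perp = [c for i, c in enumerate(coords) if i != axis]
    ctr = [c for i, c in enumerate(center) if i != axis]
    dist2 = sum((p - c) ** 2 for p, c in zip(perp, ctr))
    along = coords[axis]
    mask[(dist2 <= radius**2) & (along >= lo) & (along < hi)] = True
    return mask


@pytest.fixture(scope="session")
def cow_complete():
    return make_cow_phantom("complete", seed=3, shape=(48, 48, 48))


@pytest.fixture(scope="session")
def octa_small():
    return make_octa_phantom(seed=5, shape=(32, 32, 32))
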