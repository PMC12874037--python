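"""Topological invariants of 3D binary masks.

Computed from the cubical complex of closed unit voxels (so foreground
connectivity is the 26-neighborhood). Used as an independent check that
skeletonization preserves the topology of the vascular mask: same number of
connected components (b0) and of independent loops (b1).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["euler_characteristic", "betti_numbers"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def euler_characteristic(mask: np.ndarray) -> int:
    """Euler characteristic chi = V - E + F - C of the voxel cubical complex."""
    m = np.asarray(mask, bool)
    if m.ndim != 3:
        raise ValueError("mask must be 3D")
    nx_, ny, nz = m.shape

    def count_union(shape, offsets_axes):
        acc = np.zeros(shape, dtype=bool)
        for off in offsets_axes:
            sl = tuple(
                slice(o, o + n) for o, n in zip(off, m.shape)
            )
            acc[sl] |= m
        return int(acc.sum())

    # vertices: each voxel contributes its 8 corners
    V = count_union((nx_ + 1, ny + 1, nz + 1), [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)])
    # edges along x, y, z
    Ex = count_union((nx_, ny + 1, nz + 1), [(0, b, c) for b in (0, 1) for c in (0, 1)])
    Ey = count_union((nx_ + 1, ny, nz + 1), [(a, 0, c) for a in (0, 1) for c in (0, 1)])
    Ez = count_union((nx_ + 1, ny + 1, nz), [(a, b, 0) for a in (0, 1) for b in (0, 1)])
    # faces normal to z, y, x
    Fxy = count_union((nx_, ny, nz + 1), [(0, 0, c) for c in (0, 1)])
    Fxz = count_union((nx_, ny + 1, nz), [(0, b, 0) for b in (0, 1)])
    Fyz = count_union((nx_ + 1, ny, nz), [(a, 0, 0) for a in (0, 1)])
    C = int(m.sum())
    return V - (Ex + Ey + Ez) + (Fxy + Fxz + Fyz) - C


def betti_numbers(mask: np.ndarray) -> tuple[int, int, int]:
    """(b0, b1, b2): components, independent loops, enclosed cavities.

    b0 uses 26-connectivity; b2 counts 6-connected background components not
    reaching the (padded) border; b1 follows from chi = b0 - b1 + b2.
    """
    m = np.asarray(mask, bool)
    b0 = int(ndimage.label(m, structure=_STRUCT26)[1])
    padded = np.pad(m, 1)
    b2 = int(ndimage.label(~padded)[1]) - 1  # 6-connectivity default
    chi = euler_characteristic(m)
    b1 = b0 + b2 - chi
    return b0, b1, b2
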