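"""Topology-preserving 3D binary thinning.

Iterative border-point removal in six directional subiterations. A voxel may
be deleted only if it is a *simple point* -- deletion does not change the
number of foreground components, background components, or tunnels -- using
the local characterization: exactly one 26-connected foreground component in
the 26-neighborhood, and exactly one 6-connected background component in the
18-neighborhood touching a face neighbor. Candidates of each subiteration
are re-checked sequentially, so simultaneous deletions can never cooperate
to break topology (the failure mode of naive parallel thinning on two-voxel
-thick symmetric slabs). Line end points (exactly one foreground neighbor)
are preserved, so every component retains at least a one-voxel trace.

Numba-compiled; the first call pays a small JIT cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["thin_3d"]

# cell k = 0..26 of the 3x3x3 patch <-> offset (k//9-1, (k//3)%3-1, k%3-1)
_OFFSETS = np.array([(k // 9 - 1, (k // 3) % 3 - 1, k % 3 - 1) for k in range(27)], dtype=np.int8)
_CENTER = 13

# 26-adjacency between patch cells (for foreground components)
_ADJ26 = np.zeros((27, 27), dtype=np.bool_)
for _i in range(27):
    for _j in range(27):
        if _i == _j or _i == _CENTER or _j == _CENTER:
            continue
        _d = np.abs(_OFFSETS[_i] - _OFFSETS[_j])
        if _d.max() <= 1:
            _ADJ26[_i, _j] = True

# the 18-neighborhood: face + edge cells (corners excluded)
_N18 = np.array(
    [int(np.abs(_OFFSETS[k]).sum()) in (1, 2) and k != _CENTER for k in range(27)],
    dtype=np.bool_,
)
_FACE = np.array([int(np.abs(_OFFSETS[k]).sum()) == 1 for k in range(27)], dtype=np.bool_)

# 6-adjacency between cells, restricted to the 18-neighborhood (for background)
_ADJ6 = np.zeros((27, 27), dtype=np.bool_)
for _i in range(27):
    for _j in range(27):
        if not (_N18[_i] and _N18[_j]):
            continue
        _d = _OFFSETS[_i] - _OFFSETS[_j]
        if np.abs(_d).sum() == 1:
            _ADJ6[_i, _j] = True

# six face directions, fixed subiteration order (U, D, N, S, E, W)
_DIRECTIONS = np.array(
    [(0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0), (1, 0, 0), (-1, 0, 0)], dtype=np.int8
)

# for each direction, the 9 neighbor offsets in the half-space behind it
_BEHIND = np.zeros((6, 9, 3), dtype=np.int8)
for _di in range(6):
    _n = 0
    for _k in range(27):
        if int(_OFFSETS[_k] @ _DIRECTIONS[_di]) == -1:
            _BEHIND[_di, _n] = _OFFSETS[_k]
            _n += 1


@njit(cache=True)
def _read_patch(img, x, y, z, patch):
    for k in range(27):
        patch[k] = img[x + _OFFSETS[k, 0], y + _OFFSETS[k, 1], z + _OFFSETS[k, 2]]


@njit(cache=True)
def _is_simple(patch):
    """Simple-point test on a 27-cell patch (center assumed foreground)."""
    # foreground: one 26-component among the 26 neighbors
    n_fg = 0
    first_fg = -1
    for k in range(27):
        if k != _CENTER and patch[k]:
            n_fg += 1
            if first_fg < 0:
                first_fg = k
    if n_fg == 0:
        return False  # isolated voxel: deletion would remove a component
    visited = np.zeros(27, dtype=np.bool_)
    stack = np.empty(27, dtype=np.int64)
    top = 0
    stack[top] = first_fg
    top += 1
    visited[first_fg] = True
    while top > 0:
        top -= 1
        c = stack[top]
        for j in range(27):
            if patch[j] and not visited[j] and j != _CENTER and _ADJ26[c, j]:
                visited[j] = True
                stack[top] = j
                top += 1
    for k in range(27):
        if k != _CENTER and patch[k] and not visited[k]:
            return False  # more than one foreground component

    # background: one 6-component in N18 touching a face neighbor
    first_bg = -1
    for k in range(27):
        if _FACE[k] and not patch[k]:
            first_bg = k
            break
    if first_bg < 0:
        return False  # interior point
    visited[:] = False
    top = 0
    stack[top] = first_bg
    top += 1
    visited[first_bg] = True
    while top > 0:
        top -= 1
        c = stack[top]
        for j in range(27):
            if _N18[j] and not patch[j] and not visited[j] and _ADJ6[c, j]:
                visited[j] = True
                stack[top] = j
                top += 1
    for k in range(27):
        if _FACE[k] and not patch[k] and not visited[k]:
            return False  # a second background component touches a face
    return True


@njit(cache=True)
def _count_neighbors(patch):
    n = 0
    for k in range(27):
        if k != _CENTER and patch[k]:
            n += 1
    return n


@njit(cache=True)
def _thin_pass(img, coords, d, behind):
    """One directional subiteration with sequential re-checking.

    ``coords`` are foreground voxel coordinates (padded image); a voxel
    qualifies if its face neighbor in direction d is background. Returns the
    number of deleted voxels.
    """
    patch = np.zeros(27, dtype=np.bool_)
    # phase 1: freeze the border candidates of this direction
    n_cand = 0
    cand = np.empty((coords.shape[0], 3), dtype=np.int64)
    for i in range(coords.shape[0]):
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        if not img[x, y, z]:
            continue
        if img[x + d[0], y + d[1], z + d[2]]:
            continue  # not a border point of this direction
        cand[n_cand, 0] = x
        cand[n_cand, 1] = y
        cand[n_cand, 2] = z
        n_cand += 1
    # phase 2: sequential re-check with half-space support. A candidate may
    # only be deleted while some neighbor in the half-space behind the peel
    # direction is still foreground: a pass peels at most one layer and can
    # never eat its way along a one-voxel-thick ribbon, while diagonal
    # ribbons (whose backing neighbor is a diagonal) still thin normally.
    deleted = 0
    for i in range(n_cand):
        x, y, z = cand[i, 0], cand[i, 1], cand[i, 2]
        support = False
        for j in range(9):
            if img[x + behind[j, 0], y + behind[j, 1], z + behind[j, 2]]:
                support = True
                break
        if not support:
            continue
        _read_patch(img, x, y, z, patch)
        if _count_neighbors(patch) <= 1:
            continue  # line end point: preserved
        if _is_simple(patch):
            img[x, y, z] = False
            deleted += 1
    return deleted


@njit(cache=True)
def _thin_loop(img):
    total_deleted = 0
    while True:
        # collect current foreground once per full sweep
        n = 0
        for x in range(1, img.shape[0] - 1):
            for y in range(1, img.shape[1] - 1):
                for z in range(1, img.shape[2] - 1):
                    if img[x, y, z]:
                        n += 1
        coords = np.empty((n, 3), dtype=np.int64)
        i = 0
        for x in range(1, img.shape[0] - 1):
            for y in range(1, img.shape[1] - 1):
                for z in range(1, img.shape[2] - 1):
                    if img[x, y, z]:
                        coords[i, 0] = x
                        coords[i, 1] = y
                        coords[i, 2] = z
                        i += 1
        deleted = 0
        for di in range(6):
            deleted += _thin_pass(img, coords, _DIRECTIONS[di], _BEHIND[di])
        total_deleted += deleted
        if deleted == 0:
            return total_deleted


def thin_3d(mask: np.ndarray) -> np.ndarray:
    """Thin a 3D binary mask to a one-voxel-wide, topology-preserving skeleton."""
    m = np.asarray(mask, bool)
    if m.ndim != 3:
        raise ValueError("thin_3d expects a 3D mask")
    if not m.any():
        return np.zeros_like(m)
    padded = np.pad(m, 1).copy()
    _thin_loop(padded)
    return padded[1:-1, 1:-1, 1:-1]
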