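"""Face-seal analysis of voxelized insulator patches.

In a hexahedral FEM model an insulating patch only blocks current if every
pair of its voxels that touch do so across a full face somewhere nearby:
two voxels meeting only along an edge or at a corner leave a gap through
which current leaks around the insulator. The check below flags exactly
those configurations.
"""

from __future__ import annotations

import numpy as np


def _block_face_connected(mask_block: np.ndarray, a, b) -> bool:
    """Face-connectivity of ``a`` and ``b`` within a small boolean block."""
    shape = mask_block.shape
    visited = np.zeros(shape, dtype=bool)
    stack = [a]
    visited[a] = True
    while stack:
        cur = stack.pop()
        if cur == b:
            return True
        for ax in range(3):
            for step in (-1, 1):
                nxt = list(cur)
                nxt[ax] += step
                if 0 <= nxt[ax] < shape[ax]:
                    nxt = tuple(nxt)
                    if mask_block[nxt] and not visited[nxt]:
                        visited[nxt] = True
                        stack.append(nxt)
    return False


def find_leaks(mask: np.ndarray, max_report: int = 1000) -> list[tuple]:
    """Return voxel-index pairs of ``mask`` that touch only via edge/corner.

    A pair of set voxels that are 26-adjacent but not face-adjacent is a
    leak unless the set restricted to their 2x2x2 bounding block already
    face-connects them (e.g. a third voxel bridges the edge).
    """
    mask = np.asarray(mask, dtype=bool)
    leaks: list[tuple] = []
    idx = np.argwhere(mask)
    index_set = {tuple(i) for i in idx}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) >= 2
    ]
    for a in map(tuple, idx):
        for off in offsets:
            b = (a[0] + off[0], a[1] + off[1], a[2] + off[2])
            if b <= a or b not in index_set:
                continue
            lo = tuple(min(a[d], b[d]) for d in range(3))
            hi = tuple(max(a[d], b[d]) + 1 for d in range(3))
            block = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            a_loc = tuple(a[d] - lo[d] for d in range(3))
            b_loc = tuple(b[d] - lo[d] for d in range(3))
            if not _block_face_connected(block, a_loc, b_loc):
                leaks.append((a, b))
                if len(leaks) >= max_report:
                    return leaks
    return leaks


def is_sealed(mask: np.ndarray) -> bool:
    return len(find_leaks(mask, max_report=1)) == 0
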