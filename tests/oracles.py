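"""Brute-force reference implementations used to cross-check the package.

These deliberately avoid scipy/skimage machinery: set-based flood fill,
double-loop binning — slow but transparent.
"""

import numpy as np

_NEIGH26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
_NEIGH6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def oracle_bridge_count(cand, epi, meta):
    """Count candidate components face-adjacent to both bodies (naive BFS)."""
    cand_set = {tuple(v) for v in np.argwhere(cand)}
    epi_set = {tuple(v) for v in np.argwhere(epi)}
    meta_set = {tuple(v) for v in np.argwhere(meta)}
    seen, count = set(), 0
    for start in sorted(cand_set):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            for d in _NEIGH26:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if w in cand_set and w not in comp:
                    stack.append(w)
        seen |= comp
        touch_e = touch_m = False
        for v in comp:
            for d in _NEIGH6:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                touch_e |= w in epi_set
                touch_m |= w in meta_set
        if touch_e and touch_m:
            count += 1
    return count


def oracle_bin_counts(coords, window, origin_uv, shape, offset_ij):
    """Double-loop half-open binning of (u, v) points into tiles."""
    counts = np.zeros(shape, dtype=int)
    for i in range(shape[0]):
        for j in range(shape[1]):
            lu = origin_uv[0] + (i + offset_ij[0]) * window
            lv = origin_uv[1] + (j + offset_ij[1]) * window
            for (u, v) in coords:
                if lu <= u < lu + window and lv <= v < lv + window:
                    counts[i, j] += 1
    return counts
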