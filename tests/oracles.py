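"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library paths they are checking: connected
components by breadth-first search over explicit neighbour offsets, singular
values by eigendecomposition of the Gram matrix.
"""

from collections import deque
from itertools import product

import numpy as np


def neighbour_offsets(connectivity: int):
    if connectivity == 6:
        return [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)]
    if connectivity == 26:
        return [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    raise ValueError(connectivity)


def bfs_components(binary: np.ndarray, connectivity: int):
    """List of voxel-coordinate sets, one per connected component."""
    offsets = neighbour_offsets(connectivity)
    active = {tuple(c) for c in np.argwhere(binary)}
    seen = set()
    comps = []
    for start in sorted(active):
        if start in seen:
            continue
        comp = set()
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            comp.add(v)
            for d in offsets:
                nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if nb in active and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def bfs_peaks(values: np.ndarray, threshold: float, min_cluster: int,
              connectivity: int):
    """(peak coordinate, peak value, size) per surviving cluster, both poles."""
    out = []
    for sel in (values > threshold, values < -threshold):
        for comp in bfs_components(sel, connectivity):
            if len(comp) < min_cluster:
                continue
            peak = max(comp, key=lambda c: (abs(values[c]), c))
            out.append((peak, float(values[peak]), len(comp)))
    return out


def gram_singular_values(r: np.ndarray) -> np.ndarray:
    """Singular values via brute-force eigendecomposition of R'R."""
    ev = np.linalg.eigvalsh(r.T @ r)[::-1]
    return np.sqrt(np.clip(ev, 0.0, None))[: min(r.shape)]
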