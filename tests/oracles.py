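"""Brute-force oracles shared across test modules."""

from collections import deque

import numpy as np


def flood_fill_clusters(supra: np.ndarray, connectivity: int) -> list[frozenset]:
    """Independent BFS connected-components oracle for 3D binary volumes."""
    offsets = []
    for d in np.ndindex(3, 3, 3):
        d = np.array(d) - 1
        if not d.any():
            continue
        order = np.abs(d).sum()
        if (connectivity, order) in [(6, 1)] or (connectivity == 18 and order <= 2) \
                or connectivity == 26:
            offsets.append(d)
    seen = np.zeros_like(supra, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(supra)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            p = queue.popleft()
            comp.add(p)
            for off in offsets:
                q = tuple(np.array(p) + off)
                if all(0 <= q[i] < supra.shape[i] for i in range(3)) \
                        and supra[q] and not seen[q]:
                    seen[q] = True
                    queue.append(q)
        comps.append(frozenset(comp))
    return comps
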