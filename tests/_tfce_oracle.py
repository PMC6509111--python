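"""Brute-force TFCE oracle: pure-Python flood fill at every threshold.

Independent of the package's implementation (which uses
``scipy.ndimage.label`` and a batched normalization trick): components
are found by breadth-first search over explicit neighbor offsets.
"""

import numpy as np

_OFFSETS = {
    6: [(dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) == 1],
    26: [(dx, dy, dz)
         for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)],
}


def _components(sup: np.ndarray, connectivity: int):
    """Connected components of a boolean volume via BFS flood fill."""
    offs = _OFFSETS[connectivity]
    shape = sup.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for idx in zip(*np.nonzero(sup)):
        if seen[idx]:
            continue
        stack, comp = [idx], []
        seen[idx] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for dx, dy, dz in offs:
                w = (v[0] + dx, v[1] + dy, v[2] + dz)
                if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1]
                        and 0 <= w[2] < shape[2] and sup[w] and not seen[w]):
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


def tfce_bruteforce(stat: np.ndarray, E: float, H: float, dh: float,
                    connectivity: int = 26) -> np.ndarray:
    """Enhance the nonnegative part of ``stat`` threshold by threshold."""
    s = np.clip(np.asarray(stat, dtype=float), 0.0, None)
    out = np.zeros_like(s)
    peak = s.max()
    if peak <= 0:
        return out
    h = dh
    while h <= peak + 1e-12:
        for comp in _components(s >= h, connectivity):
            contribution = (len(comp) ** E) * (h ** H) * dh
            for v in comp:
                out[v] += contribution
        h += dh
    return out
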