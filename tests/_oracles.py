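"""Brute-force reference implementations used only as test oracles.

These deliberately use naive algorithms (explicit loops, flood fill,
threshold search) independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def dice_brute(a: np.ndarray, b: np.ndarray) -> float:
    """Dice by explicit voxel counting; nan when both masks empty."""
    na = nb = ninter = 0
    for va, vb in zip(a.ravel(), b.ravel()):
        na += bool(va)
        nb += bool(vb)
        ninter += bool(va) and bool(vb)
    if na == 0 and nb == 0:
        return float("nan")
    if na == 0 or nb == 0:
        return 0.0
    return ninter / ((na + nb) / 2)


def spillover_brute(activation: np.ndarray, other_mask: np.ndarray) -> float:
    total = outside = 0
    for act, m in zip(activation.ravel(), other_mask.ravel()):
        if act:
            total += 1
            if not m:
                outside += 1
    if total == 0:
        return float("nan")
    return 100.0 * outside / total


def pearson_brute(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r from the definition (explicit sums)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    am, bm = a.mean(), b.mean()
    num = float(((a - am) * (b - bm)).sum())
    den = float(np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum()))
    return num / den


def _neighbors(idx: tuple[int, ...], shape: tuple[int, ...], connectivity: int):
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                dist = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and dist > 1:
                    continue
                if connectivity == 18 and dist > 2:
                    continue
                offsets.append((dx, dy, dz))
    x, y, z = idx
    for dx, dy, dz in offsets:
        nx, ny, nz = x + dx, y + dy, z + dz
        if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
            yield (nx, ny, nz)


def label_brute(binary: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a 3-D binary array by BFS flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros(binary.shape, dtype=bool)
    components = []
    for idx in zip(*np.nonzero(binary)):
        if seen[idx]:
            continue
        queue = [idx]
        seen[idx] = True
        comp = set()
        while queue:
            cur = queue.pop()
            comp.add(cur)
            for nb in _neighbors(cur, binary.shape, connectivity):
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(comp)
    return components


def bh_reject_brute(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up by explicit threshold search."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject
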