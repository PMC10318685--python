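"""Set algebra on half-open genomic intervals.

Intervals are ``(k, 2)`` integer numpy arrays of ``[start, end)`` rows.
All functions return *normalized* arrays: sorted by start, disjoint, with
adjacent (abutting) intervals merged. Point-in-set queries are vectorized
via searchsorted on the flattened boundary array.
"""

from __future__ import annotations

import numpy as np

EMPTY = np.empty((0, 2), dtype=np.int64)


def as_intervals(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=np.int64)
    if a.size == 0:
        return EMPTY.copy()
    a = a.reshape(-1, 2)
    if np.any(a[:, 0] >= a[:, 1]):
        raise ValueError("interval start must be < end")
    return a


def merge(arr) -> np.ndarray:
    """Sort, merge overlapping and abutting intervals."""
    a = as_intervals(arr)
    if len(a) <= 1:
        return a
    a = a[np.argsort(a[:, 0], kind="stable")]
    out = [a[0].copy()]
    for s, e in a[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e], dtype=np.int64))
    return np.array(out, dtype=np.int64)


def total_bp(arr) -> int:
    a = as_intervals(arr)
    if len(a) == 0:
        return 0
    return int((a[:, 1] - a[:, 0]).sum())


def complement(arr, length: int) -> np.ndarray:
    """Complement within [0, length)."""
    a = merge(arr)
    bounds = np.concatenate([[0], a.ravel(), [length]])
    pairs = bounds.reshape(-1, 2)
    keep = pairs[:, 0] < pairs[:, 1]
    return pairs[keep].astype(np.int64)


def intersect(a, b) -> np.ndarray:
    """Intersection of two interval sets."""
    a, b = merge(a), merge(b)
    if len(a) == 0 or len(b) == 0:
        return EMPTY.copy()
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64) if out else EMPTY.copy()


def subtract(a, b) -> np.ndarray:
    """Portions of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    hi = int(max(a[-1, 1], b[-1, 1]))
    return intersect(a, complement(b, hi))


def contains(arr, positions) -> np.ndarray:
    """Boolean mask: which positions fall inside the interval set."""
    a = merge(arr)
    pos = np.asarray(positions, dtype=np.int64)
    if len(a) == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(a.ravel(), pos, side="right")
    return idx % 2 == 1


def sample_positions(arr, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` positions uniformly over the union of intervals."""
    a = merge(arr)
    if len(a) == 0:
        if n:
            raise ValueError("cannot sample from an empty interval set")
        return np.empty(0, dtype=np.int64)
    lens = a[:, 1] - a[:, 0]
    cum = np.concatenate([[0], np.cumsum(lens)])
    offsets = rng.integers(0, cum[-1], size=n)
    which = np.searchsorted(cum, offsets, side="right") - 1
    return a[which, 0] + (offsets - cum[which])
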