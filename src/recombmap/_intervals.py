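"""Half-open integer interval arithmetic on ``(n, 2)`` numpy arrays.

All genomic intervals in this package are 0-based, half-open ``[start, end)``.
These are the shared primitives behind masks, segment trimming and
bp-weighted binning.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "normalize",
    "subtract",
    "intersect",
    "total_length",
    "clip",
    "bin_weighted",
]


def as_intervals(iv) -> np.ndarray:
    a = np.asarray(iv, dtype=np.int64)
    if a.size == 0:
        return a.reshape(0, 2)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("intervals must have shape (n, 2)")
    return a


def normalize(iv) -> np.ndarray:
    """Sort by start and merge overlapping or abutting intervals.

    Raises ``ValueError`` on empty (end <= start) intervals.
    """
    a = as_intervals(iv)
    if a.shape[0] == 0:
        return a
    if np.any(a[:, 1] <= a[:, 0]):
        raise ValueError("interval with end <= start")
    a = a[np.argsort(a[:, 0], kind="stable")]
    out = []
    cs, ce = a[0]
    for s, e in a[1:]:
        if s <= ce:  # overlap or abut
            ce = max(ce, e)
        else:
            out.append((cs, ce))
            cs, ce = s, e
    out.append((cs, ce))
    return np.array(out, dtype=np.int64)


def total_length(iv) -> int:
    a = as_intervals(iv)
    if a.shape[0] == 0:
        return 0
    return int(np.sum(a[:, 1] - a[:, 0]))


def clip(iv, lo: int, hi: int) -> np.ndarray:
    """Intersect intervals with [lo, hi), dropping empties."""
    a = as_intervals(iv).copy()
    if a.shape[0] == 0:
        return a
    a[:, 0] = np.maximum(a[:, 0], lo)
    a[:, 1] = np.minimum(a[:, 1], hi)
    return a[a[:, 1] > a[:, 0]]


def subtract(iv, mask) -> np.ndarray:
    """Pieces of ``iv`` not covered by ``mask``.

    ``iv`` need not be disjoint; each input interval is trimmed
    independently and pieces are returned in input order (so callers can
    track which piece came from which segment via :func:`subtract_indexed`).
    """
    pieces, _ = subtract_indexed(iv, mask)
    return pieces


def subtract_indexed(iv, mask) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`subtract` but also returns source-row indices."""
    a = as_intervals(iv)
    m = normalize(mask) if as_intervals(mask).shape[0] else as_intervals(mask)
    if a.shape[0] == 0:
        return a, np.zeros(0, dtype=np.int64)
    if m.shape[0] == 0:
        return a.copy(), np.arange(a.shape[0], dtype=np.int64)
    out = []
    idx = []
    for i, (s, e) in enumerate(a):
        cur = s
        # mask intervals that can overlap [s, e)
        j0 = np.searchsorted(m[:, 1], s, side="right")
        for ms, me in m[j0:]:
            if ms >= e:
                break
            if ms > cur:
                out.append((cur, ms))
                idx.append(i)
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
            idx.append(i)
    if not out:
        return np.zeros((0, 2), dtype=np.int64), np.zeros(0, dtype=np.int64)
    return np.array(out, dtype=np.int64), np.array(idx, dtype=np.int64)


def intersect(iv, mask) -> np.ndarray:
    """Pieces of ``iv`` covered by ``mask``."""
    a = as_intervals(iv)
    m = normalize(mask) if as_intervals(mask).shape[0] else as_intervals(mask)
    if a.shape[0] == 0 or m.shape[0] == 0:
        return np.zeros((0, 2), dtype=np.int64)
    out = []
    for s, e in a:
        j0 = np.searchsorted(m[:, 1], s, side="right")
        for ms, me in m[j0:]:
            if ms >= e:
                break
            out.append((max(s, ms), min(e, me)))
    if not out:
        return np.zeros((0, 2), dtype=np.int64)
    return np.array(out, dtype=np.int64)


def bin_weighted(starts, ends, values, resolution: int, n_bins: int):
    """bp-weighted accumulation of piecewise-constant values into fixed bins.

    Bins are ``[k*resolution, (k+1)*resolution)`` for ``k in range(n_bins)``,
    anchored at coordinate 0.  Returns ``(weighted_sum, covered_bp)`` arrays
    of length ``n_bins``; the bp-weighted mean per bin is their ratio where
    coverage is positive.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    keep = ends > starts
    starts, ends, values = starts[keep], ends[keep], values[keep]
    wsum = np.zeros(n_bins)
    cov = np.zeros(n_bins)
    if starts.size == 0:
        return wsum, cov
    first = starts // resolution
    last = (ends - 1) // resolution
    counts = (last - first + 1).astype(np.int64)
    n_pieces = int(counts.sum())
    src = np.repeat(np.arange(starts.size), counts)
    offsets = np.arange(n_pieces) - np.repeat(np.cumsum(counts) - counts, counts)
    piece_bin = first[src] + offsets
    ps = np.maximum(starts[src], piece_bin * resolution)
    pe = np.minimum(ends[src], (piece_bin + 1) * resolution)
    ln = (pe - ps).astype(np.float64)
    inside = (piece_bin >= 0) & (piece_bin < n_bins)
    np.add.at(wsum, piece_bin[inside], ln[inside] * values[src][inside])
    np.add.at(cov, piece_bin[inside], ln[inside])
    return wsum, cov
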