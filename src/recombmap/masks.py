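"""Marker-density analysis masks and their application to maps and segments.

Regions where an array leaves too few markers produce unreliable LD-based
rate estimates and pile up spurious IBD segments; the mask flags every
500 kb tiling window (50 kb step) holding fewer than 15 markers, and
applying it to a map sets the genetic distance across masked bp to zero.
"""

from __future__ import annotations

import math

import numpy as np

from . import _intervals
from .mapio import GeneticMap, MaskSet


def build_density_mask(
    marker_positions,
    chrom_length: int,
    window_bp: int = 500_000,
    step_bp: int = 50_000,
    min_markers: int = 15,
    chrom: str = "1",
    granularity: str = "window",
) -> MaskSet:
    """Flag low-marker-density windows and union them into a mask.

    Every window ``[s, s + window_bp)`` with ``s`` on the ``step_bp`` grid
    and fewer than ``min_markers`` markers (half-open membership) is
    flagged.  A trailing partial window is judged against a proportionally
    scaled threshold ``ceil(min_markers * width / window_bp)``.  With
    ``granularity="window"`` (default) the whole flagged window is masked;
    ``"step"`` masks only the window's leading ``step_bp`` increment.
    """
    pos = np.asarray(marker_positions, dtype=np.int64)
    if pos.size > 1 and np.any(np.diff(pos) < 0):
        raise ValueError("marker positions must be sorted")
    if chrom_length < window_bp:
        raise ValueError("chrom_length must be at least one full window")
    if granularity not in ("window", "step"):
        raise ValueError("granularity must be 'window' or 'step'")
    flagged = []
    for s in range(0, chrom_length, step_bp):
        width = min(window_bp, chrom_length - s)
        if width <= 0:
            break
        thr = min_markers if width == window_bp else math.ceil(min_markers * width / window_bp)
        n = int(np.searchsorted(pos, s + width, side="left") - np.searchsorted(pos, s, side="left"))
        if n < thr:
            end = s + width if granularity == "window" else min(s + step_bp, chrom_length)
            flagged.append((s, end))
    if not flagged:
        return MaskSet()
    return MaskSet({chrom: flagged})


def apply_mask_to_map(gmap: GeneticMap, mask: MaskSet) -> GeneticMap:
    """Zero the genetic distance over masked bp.

    Map intervals are split at the mask boundaries and the rate on every
    piece inside the mask is set to 0, so partially overlapped intervals
    lose exactly the genetic length of their overlapped bp, interpolation
    stays exact away from the mask, and the total map length drops by
    exactly the masked genetic length.
    """
    iv = mask.intervals(gmap.chrom)
    if iv.shape[0] == 0:
        return gmap
    pos = gmap.positions
    cuts = iv.ravel()
    cuts = cuts[(cuts > pos[0]) & (cuts < pos[-1])]
    newpos = np.unique(np.concatenate([pos, cuts]))
    cum = gmap.interpolate_cM(newpos)
    rate = np.diff(cum) / (np.diff(newpos) / 1e6)
    mid = (newpos[:-1] + newpos[1:]) // 2
    j = np.searchsorted(iv[:, 0], mid, side="right") - 1
    inside = (j >= 0) & (mid < iv[np.maximum(j, 0), 1])
    rate[inside] = 0.0
    return GeneticMap.from_rates(gmap.chrom, newpos, rate, start_cM=float(gmap.cum_cM[0]))


def mask_intersect(intervals, mask: MaskSet, chrom: str) -> np.ndarray:
    """Subtract the mask from intervals (standard half-open subtraction).

    Segments containing a mask in their interior are split; segments fully
    inside the mask are removed.
    """
    return _intervals.subtract(intervals, mask.intervals(chrom))


def masked_length(mask: MaskSet, gmap: GeneticMap | None = None):
    """Total masked extent in bp and, given a map, in cM."""
    bp = mask.total_bp()
    if gmap is None:
        return bp
    iv = mask.intervals(gmap.chrom)
    cm = float(np.sum(gmap.interpolate_cM(iv[:, 1]) - gmap.interpolate_cM(iv[:, 0]))) if iv.size else 0.0
    return bp, cm
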