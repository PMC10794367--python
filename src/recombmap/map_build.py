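"""Assemble windowed rho estimates into chromosome maps and rescale to cM.

Pipeline: overlapping per-window estimates of the population-scaled rate
rho = 4*Ne*r are stitched (distal half of each overlap discarded), the
dimensionless factor 4Ne is estimated by regressing rho on a reference
map's rate in 5 Mb windows, and the stitched track is divided by 4Ne to
give per-interval rates in cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _intervals
from .mapio import GeneticMap, MaskSet, RhoWindowSet


@dataclass(frozen=True, eq=False)
class RhoTrack:
    """Genome-contiguous stitched rho estimates (per kb) per SNP interval."""

    chrom: str
    snp_positions: np.ndarray
    rho_per_kb: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.snp_positions, dtype=np.int64)
        rho = np.asarray(self.rho_per_kb, dtype=np.float64)
        object.__setattr__(self, "snp_positions", pos)
        object.__setattr__(self, "rho_per_kb", rho)
        if rho.size != pos.size - 1:
            raise ValueError("need one rho per interval")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions not strictly increasing")
        if np.any(rho < 0):
            raise ValueError("negative rho")


@dataclass(frozen=True)
class NeFit:
    """No-intercept OLS fit of rho on reference rate; slope is 4Ne."""

    fourNe: float
    n_windows: int
    r_squared: float

    def __post_init__(self):
        if self.fourNe <= 0:
            raise ValueError("fourNe must be positive")
        if self.n_windows < 2:
            raise ValueError("need at least 2 windows")


@dataclass(frozen=True, eq=False)
class BinnedMap:
    """Fixed-width bins (anchored at 0) of bp-weighted mean rate."""

    resolution_bp: int
    mean_rate: np.ndarray
    missing: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean_rate", np.asarray(self.mean_rate, dtype=np.float64))
        object.__setattr__(self, "missing", np.asarray(self.missing, dtype=bool))
        if self.mean_rate.shape != self.missing.shape:
            raise ValueError("mean_rate/missing shape mismatch")

    @property
    def n_bins(self) -> int:
        return int(self.mean_rate.size)


def stitch_windows(windows: RhoWindowSet) -> RhoTrack:
    """Combine overlapping windows, discarding the distal half of each overlap.

    For an overlap of n shared SNPs the boundary is the shared SNP at index
    floor(n/2) (counted from the left): the left window contributes all
    intervals ending at or before the boundary SNP, the right window all
    intervals starting at or after it.  Every input interval appears in the
    output exactly once; adjacent windows must share their declared overlap
    positions verbatim.
    """
    wins = list(windows)
    if not wins:
        raise ValueError("empty window set")
    pos_parts = []
    rho_parts = []
    for i, w in enumerate(wins):
        start_idx = 0
        if i > 0:
            n_ov = w.n_overlap_left
            prev = wins[i - 1]
            if n_ov < 1:
                raise ValueError(f"window {w.window_index}: missing left overlap")
            shared_prev = prev.snp_positions[-n_ov:]
            shared_cur = w.snp_positions[:n_ov]
            if not np.array_equal(shared_prev, shared_cur):
                div = int(np.argmax(shared_prev != shared_cur))
                raise ValueError(
                    f"overlap mismatch between windows {prev.window_index} and "
                    f"{w.window_index}: first divergent position "
                    f"{shared_cur[div]} (expected {shared_prev[div]})"
                )
            start_idx = n_ov // 2  # boundary SNP; odd overlaps floor from the left
        end_idx = w.snp_positions.size - 1  # last interval start index + 1
        if i + 1 < len(wins):
            end_idx = w.snp_positions.size - w.n_overlap_right + w.n_overlap_right // 2
        pos_parts.append(w.snp_positions[start_idx:end_idx])
        rho_parts.append(w.rho_per_kb[start_idx:end_idx])
    pos_parts.append(wins[-1].snp_positions[-1:])
    positions = np.concatenate(pos_parts)
    rho = np.concatenate(rho_parts)
    return RhoTrack(chrom=wins[0].chrom, snp_positions=positions, rho_per_kb=rho)


def _masked_pieces(positions, values, mask_iv):
    """Split per-interval values into unmasked (start, end, value) pieces."""
    starts = positions[:-1]
    ends = positions[1:]
    if mask_iv.shape[0] == 0:
        return starts, ends, values
    iv = np.stack([starts, ends], axis=1)
    pieces, src = _intervals.subtract_indexed(iv, mask_iv)
    return pieces[:, 0], pieces[:, 1], values[src]


def estimate_fourNe(
    rho: RhoTrack,
    reference: GeneticMap,
    window_bp: int = 5_000_000,
    mask: MaskSet | None = None,
    with_intercept: bool = False,
) -> NeFit:
    """Regress windowed rho on windowed reference rate; the slope is 4Ne.

    The reference map's rate is evaluated over the rho track's own SNP
    intervals, so both tracks are averaged over the same physical support.
    Within each ``window_bp`` window both are reduced to bp-weighted means
    (masked bp excluded), converted to common per-bp units
    (rho/bp = rho_per_kb / 1000; r/bp = cM/Mb * 1e-8), and fit by ordinary
    least squares through the origin (the model rho = 4Ne * r has no
    intercept; ``with_intercept`` fits one and still reports the slope).
    """
    mask_iv = mask.intervals(rho.chrom) if mask is not None else np.zeros((0, 2), dtype=np.int64)
    hi = int(rho.snp_positions[-1])
    n_win = -(-hi // window_bp)

    pos = rho.snp_positions
    ref_cum = reference.interpolate_cM(pos)
    d_bp = np.diff(pos).astype(float)
    ref_r_per_bp = np.diff(ref_cum) / 100.0 / d_bp

    def _means(values):
        s, e, v = _masked_pieces(pos, values, mask_iv)
        wsum, cov = _intervals.bin_weighted(s, e, v, window_bp, n_win)
        return wsum, cov

    rsum, rcov = _means(rho.rho_per_kb / 1000.0)
    msum, mcov = _means(ref_r_per_bp)
    ok = (rcov > 0) & (mcov > 0)
    if int(ok.sum()) < 2:
        raise ValueError("fewer than 2 usable windows for the 4Ne regression")
    x = msum[ok] / mcov[ok]
    y = rsum[ok] / rcov[ok]
    if np.all(x == 0):
        raise ValueError("reference rate is zero in every usable window")
    if with_intercept:
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        yhat = slope * x
        ss_tot = float(np.sum(y**2))
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return NeFit(fourNe=float(slope), n_windows=int(ok.sum()), r_squared=r2)


def rescale_to_cM(rho: RhoTrack, fit: NeFit) -> GeneticMap:
    """Divide rho by 4Ne: rate(cM/Mb) = (rho_per_kb/1000)/4Ne * 1e8.

    Cumulative cM starts at 0 at the first SNP.
    """
    rate = rho.rho_per_kb / 1000.0 / fit.fourNe * 1e8
    return GeneticMap.from_rates(rho.chrom, rho.snp_positions, rate)


def bin_map(
    obj: GeneticMap | RhoTrack,
    resolution_bp: int,
    mask: MaskSet | None = None,
    chrom_length: int | None = None,
    missing_mask_fraction: float = 0.9,
) -> BinnedMap:
    """bp-weighted mean rate in fixed bins anchored at coordinate 0.

    Bins with no unmasked covered bp, or with more than
    ``missing_mask_fraction`` of their span masked, are flagged missing.
    Works on a rescaled map (rates in cM/Mb) or directly on a rho track
    (rates in rho/kb).
    """
    if isinstance(obj, GeneticMap):
        positions, values, chrom = obj.positions, obj.rate_cM_per_Mb, obj.chrom
    else:
        positions, values, chrom = obj.snp_positions, obj.rho_per_kb, obj.chrom
    hi = chrom_length if chrom_length is not None else int(positions[-1])
    n_bins = -(-hi // resolution_bp)
    mask_iv = mask.intervals(chrom) if mask is not None else np.zeros((0, 2), dtype=np.int64)
    s, e, v = _masked_pieces(positions, values, mask_iv)
    wsum, cov = _intervals.bin_weighted(s, e, v, resolution_bp, n_bins)
    missing = cov <= 0
    if mask_iv.shape[0]:
        ones = np.ones(mask_iv.shape[0])
        msum, _ = _intervals.bin_weighted(mask_iv[:, 0], mask_iv[:, 1], ones, resolution_bp, n_bins)
        missing |= msum > missing_mask_fraction * resolution_bp
    mean = np.full(n_bins, np.nan)
    np.divide(wsum, cov, out=mean, where=~missing)
    return BinnedMap(resolution_bp=int(resolution_bp), mean_rate=mean, missing=missing)
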