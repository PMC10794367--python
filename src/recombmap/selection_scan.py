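"""EHH / iHS selection scan and its sensitivity to the genetic map.

For a core SNP, EHH at a flanking SNP is the probability that two random
carrier haplotypes of the core allele are identical over the spanned
interval.  iHH integrates EHH against genetic distance (trapezoid rule on
the cM scale) outward in both directions until EHH falls below a cutoff;
the unstandardized score is iHS = ln(iHH_ancestral / iHH_derived), which a
uniform rescaling of the map leaves unchanged.  Scores are z-normalized
within derived-allele-frequency bins; the map-sensitivity analysis flags
SNPs that are extreme under one map (|Z| > 4) but unremarkable under the
other (|Z| < 2) and compares their count to a same-map subsample
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .mapio import GeneticMap


@dataclass(frozen=True, eq=False)
class HaplotypeMatrix:
    """Phased 0/1 alleles (1 = derived), n_hap x n_snp."""

    haps: np.ndarray
    positions: np.ndarray
    chrom: str = "1"

    def __post_init__(self):
        h = np.ascontiguousarray(np.asarray(self.haps, dtype=np.uint8))
        p = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "haps", h)
        object.__setattr__(self, "positions", p)
        if h.ndim != 2 or p.size != h.shape[1]:
            raise ValueError("haps must be (n_hap, n_snp) matching positions")
        if p.size > 1 and np.any(np.diff(p) <= 0):
            raise ValueError("positions not strictly increasing")
        if not np.isin(h, (0, 1)).all():
            raise ValueError("alleles must be 0/1")

    @property
    def n_hap(self):
        return self.haps.shape[0]

    @property
    def n_snp(self):
        return self.haps.shape[1]


def ehh(hm: HaplotypeMatrix, core_snp: int, core_allele: int):
    """EHH curves outward from the core among carriers of ``core_allele``.

    Returns ``(left, right)``: EHH at each flanking SNP walking to lower /
    higher positions, each starting with 1.0 at the core.  Non-increasing
    outward by construction.
    """
    carriers = np.flatnonzero(hm.haps[:, core_snp] == core_allele)
    k = carriers.size
    if k < 2:
        raise ValueError("need at least 2 carrier haplotypes")
    out = []
    for direction in (-1, +1):
        curve = [1.0]
        key = np.zeros(k, dtype=np.int64)
        j = core_snp
        while 0 <= j + direction < hm.n_snp:
            j += direction
            key = key * 2 + hm.haps[carriers, j]
            _, key = np.unique(key, return_inverse=True)  # compress to small ints
            counts = np.bincount(key)
            hom = float(np.sum(counts * (counts - 1) / 2))
            curve.append(hom / (k * (k - 1) / 2))
        out.append(np.array(curve))
    return out[0], out[1]


@njit(cache=True)
def _ihh_side(haps, carriers, pos, cm, core, direction, cutoff, max_gap):  # pragma: no cover
    """Trapezoid iHH on one side of the core.

    Returns (area, status): status 0 = stopped below cutoff, -1 = hit the
    chromosome end first, -2 = crossed a physical gap > max_gap.
    """
    k = carriers.size
    npairs = k * (k - 1) / 2.0
    labels = np.zeros(k, np.int64)
    tmp = np.empty(k, np.int64)
    ehh_prev = 1.0
    area = 0.0
    j = core
    n_snp = haps.shape[1]
    while True:
        jn = j + direction
        if jn < 0 or jn >= n_snp:
            return area, -1
        if abs(pos[jn] - pos[j]) > max_gap:
            return area, -2
        for i in range(k):
            tmp[i] = labels[i] * 2 + haps[carriers[i], jn]
        order = np.argsort(tmp, kind="mergesort")
        hom = 0.0
        rank = 0
        run = 1
        prev = tmp[order[0]]
        labels[order[0]] = 0
        for t in range(1, k):
            v = tmp[order[t]]
            if v == prev:
                run += 1
            else:
                hom += run * (run - 1) / 2.0
                rank += 1
                run = 1
                prev = v
            labels[order[t]] = rank
        hom += run * (run - 1) / 2.0
        e = hom / npairs
        area += abs(cm[jn] - cm[j]) * (ehh_prev + e) / 2.0
        ehh_prev = e
        j = jn
        if e < cutoff:
            return area, 0


def ihs_unstandardized(
    hm: HaplotypeMatrix,
    gmap: GeneticMap,
    ehh_cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Unstandardized iHS per SNP.

    iHH is integrated outward in both directions for derived and ancestral
    carriers, truncated at the first flanking SNP where EHH drops below
    ``ehh_cutoff`` (the final trapezoid segment is included).  A SNP is
    skipped — counted in ``attrs["n_skipped"]`` — if either integration
    hits the chromosome end before the cutoff, crosses a physical gap
    larger than ``max_gap_bp``, or its minor allele frequency is below
    ``min_maf`` (the reference scan default; at least 2 carriers of each
    allele are always required).
    """
    lo, hi = gmap.span
    if hm.positions[0] < lo or hm.positions[-1] > hi:
        raise ValueError("map does not cover the SNP positions")
    cm = gmap.interpolate_cM(hm.positions)
    pos = hm.positions
    haps = hm.haps
    n_hap = hm.n_hap
    min_carriers = max(2, int(np.ceil(min_maf * n_hap)))
    rows = []
    n_skipped = 0
    for s in range(hm.n_snp):
        n_der = int(haps[:, s].sum())
        if n_der < min_carriers or n_hap - n_der < min_carriers:
            n_skipped += 1
            continue
        ihh = {}
        bad = False
        for allele in (1, 0):
            carriers = np.flatnonzero(haps[:, s] == allele)
            total = 0.0
            for direction in (-1, 1):
                area, status = _ihh_side(
                    haps, carriers, pos, cm, s, direction, ehh_cutoff, max_gap_bp
                )
                if status != 0:
                    bad = True
                    break
                total += area
            if bad:
                break
            ihh[allele] = total
        if bad or ihh[1] <= 0 or ihh[0] <= 0:
            n_skipped += 1
            continue
        rows.append((int(pos[s]), n_der / n_hap, ihh[1], ihh[0], np.log(ihh[0] / ihh[1])))
    df = pd.DataFrame(rows, columns=["pos", "freq", "ihh_derived", "ihh_ancestral", "ihs"])
    df.attrs["n_skipped"] = n_skipped
    return df


def normalize_ihs(records: pd.DataFrame, n_freq_bins: int = 50) -> pd.DataFrame:
    """Z-normalize iHS within equal-width derived-allele-frequency bins.

    Bins with fewer than 2 SNPs are merged with their left neighbor (right
    neighbor for the first bin).  The per-bin z-score uses the population
    SD, so a single-bin input has mean 0 and SD 1 exactly.
    """
    if len(records) == 0:
        out = records.copy()
        out["z"] = np.array([], dtype=float)
        return out
    edges = np.linspace(0.0, 1.0, n_freq_bins + 1)
    idx = np.clip(np.digitize(records["freq"], edges) - 1, 0, n_freq_bins - 1)
    # merge bins with < 2 SNPs into their neighbor: sweep left to right,
    # closing a group once it holds >= 2 SNPs; a short trailing group joins
    # the previous one
    counts = np.bincount(idx, minlength=n_freq_bins)
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_n = 0
    for b in range(n_freq_bins):
        cur.append(b)
        cur_n += counts[b]
        if cur_n >= 2:
            groups.append(cur)
            cur, cur_n = [], 0
    if cur:
        if groups and cur_n < 2:
            groups[-1].extend(cur)
        else:
            groups.append(cur)
    labels = np.empty(n_freq_bins, dtype=int)
    for g, members in enumerate(groups):
        labels[members] = g
    bin_of = labels[idx]
    ihs = records["ihs"].to_numpy()
    z = np.empty_like(ihs)
    for b in np.unique(bin_of):
        sel = bin_of == b
        mu = ihs[sel].mean()
        sd = ihs[sel].std()
        z[sel] = (ihs[sel] - mu) / sd if sd > 0 else 0.0
    out = records.copy()
    out["z"] = z
    return out


def ihs_scan(hm: HaplotypeMatrix, gmap: GeneticMap, n_freq_bins: int = 50, **kw) -> pd.DataFrame:
    """Convenience: unstandardized scan followed by frequency-bin normalization."""
    return normalize_ihs(ihs_unstandardized(hm, gmap, **kw), n_freq_bins=n_freq_bins)


def cross_map_discordance(
    z_a: pd.DataFrame,
    z_b: pd.DataFrame,
    hi: float = 4.0,
    lo: float = 2.0,
    cluster_bp: int = 100_000,
) -> dict:
    """SNPs extreme under one map but unremarkable under the other.

    Returns the two directional sets (|Z_a| > hi & |Z_b| < lo, and the
    mirror), each with its positions clustered into loci at
    ``cluster_bp``, plus the union count.
    """
    merged = z_a[["pos", "z"]].merge(z_b[["pos", "z"]], on="pos", suffixes=("_a", "_b"))
    za = merged["z_a"].to_numpy()
    zb = merged["z_b"].to_numpy()
    a_not_b = merged.loc[(np.abs(za) > hi) & (np.abs(zb) < lo), "pos"].to_numpy()
    b_not_a = merged.loc[(np.abs(zb) > hi) & (np.abs(za) < lo), "pos"].to_numpy()

    def _loci(positions):
        if positions.size == 0:
            return []
        positions = np.sort(positions)
        loci = [[positions[0], positions[0]]]
        for p in positions[1:]:
            if p - loci[-1][1] <= cluster_bp:
                loci[-1][1] = p
            else:
                loci.append([p, p])
        return [tuple(l) for l in loci]

    return {
        "a_not_b": np.sort(a_not_b),
        "b_not_a": np.sort(b_not_a),
        "loci_a_not_b": _loci(a_not_b),
        "loci_b_not_a": _loci(b_not_a),
        "n_discordant": int(a_not_b.size + b_not_a.size),
        "n_compared": len(merged),
    }


def permutation_null(
    hm: HaplotypeMatrix,
    gmap: GeneticMap,
    n_perm: int,
    subset_size: int,
    seed: int,
    hi: float = 4.0,
    lo: float = 2.0,
    n_freq_bins: int = 50,
    force_identical: bool = False,
    **ihs_kw,
) -> dict:
    """Null distribution of discordant-SNP counts under one map.

    Each permutation draws two disjoint random haplotype subsets of
    ``subset_size``, runs the full normalized scan on each under the SAME
    map, and counts SNPs meeting the discordance criterion — the
    between-run variability one would see with no map difference at all.
    ``force_identical`` reuses one subset for both runs (a self-check that
    must yield zero).
    """
    if not force_identical and 2 * subset_size > hm.n_hap:
        raise ValueError("need 2*subset_size <= n_hap for disjoint subsets")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9]))
    counts = np.zeros(n_perm, dtype=np.int64)
    for i in range(n_perm):
        pick = rng.choice(hm.n_hap, size=(subset_size if force_identical else 2 * subset_size),
                          replace=False)
        s1 = pick[:subset_size]
        s2 = s1 if force_identical else pick[subset_size:]
        z1 = ihs_scan(
            HaplotypeMatrix(hm.haps[s1], hm.positions, hm.chrom), gmap, n_freq_bins, **ihs_kw
        )
        z2 = ihs_scan(
            HaplotypeMatrix(hm.haps[s2], hm.positions, hm.chrom), gmap, n_freq_bins, **ihs_kw
        )
        counts[i] = cross_map_discordance(z1, z2, hi=hi, lo=lo)["n_discordant"]
    return {"counts": counts, "mean": float(counts.mean()) if n_perm else np.nan}
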