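"""Landscape similarity across populations: correlations and hotspot sharing.

Maps are compared after binning to a common resolution (bp-weighted mean
rate, mask-aware, see :func:`recombmap.map_build.bin_map`).  Concordance is
the Pearson correlation over jointly non-missing bins; hotspots are the
top-q fraction of 50 kb bins by mean rate, and sharing between two maps is
the fraction of one map's hotspots found in the other's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .map_build import BinnedMap, bin_map
from .mapio import MaskSet


@dataclass(frozen=True)
class HotspotSet:
    resolution_bp: int
    quantile: float
    bins: frozenset
    n_nonmissing: int


def correlate_maps(a: BinnedMap, b: BinnedMap) -> float:
    """Pearson correlation of mean rates over jointly non-missing bins."""
    if a.resolution_bp != b.resolution_bp:
        raise ValueError("maps binned at different resolutions")
    n = min(a.n_bins, b.n_bins)
    ok = ~a.missing[:n] & ~b.missing[:n]
    if int(ok.sum()) < 3:
        raise ValueError("fewer than 3 jointly non-missing bins")
    x = a.mean_rate[:n][ok]
    y = b.mean_rate[:n][ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the maps")
    return float(np.corrcoef(x, y)[0, 1])


def call_hotspots(binned: BinnedMap, q: float) -> HotspotSet:
    """Top ceil(q * n_nonmissing) bins by mean rate.

    Ties at the threshold are broken toward the lower bin index, so the
    call is deterministic.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    idx = np.flatnonzero(~binned.missing)
    n = idx.size
    if n == 0:
        raise ValueError("no non-missing bins")
    k = int(np.ceil(q * n))
    rates = binned.mean_rate[idx]
    order = np.lexsort((idx, -rates))  # by rate desc, then index asc
    chosen = idx[order[:k]]
    return HotspotSet(
        resolution_bp=binned.resolution_bp,
        quantile=q,
        bins=frozenset(int(i) for i in chosen),
        n_nonmissing=n,
    )


def hotspot_sharing(a: HotspotSet, b: HotspotSet) -> float:
    """Proportion of shared hotspots, |a & b| / |a|.

    Hotspot counts are equal by construction at a common quantile, so the
    measure is symmetric.
    """
    if a.resolution_bp != b.resolution_bp or a.quantile != b.quantile:
        raise ValueError("hotspot sets built at different resolution or quantile")
    if not a.bins:
        raise ValueError("empty hotspot set")
    return len(a.bins & b.bins) / len(a.bins)


def compare_suite(
    maps: dict,
    resolutions=(10_000, 50_000, 100_000, 1_000_000, 5_000_000),
    q_list=(0.01, 0.10),
    mask: MaskSet | None = None,
    chrom_length: int | None = None,
) -> dict:
    """Pairwise correlation matrices per resolution and sharing matrices per q.

    ``maps`` is a name -> GeneticMap/RhoTrack dict.  Returns
    ``{"correlation": {res: DataFrame}, "sharing": {q: DataFrame}}``;
    sharing uses 50 kb bins as in the hotspot definition.
    """
    names = list(maps)
    out_corr = {}
    for res in resolutions:
        binned = {n: bin_map(maps[n], res, mask=mask, chrom_length=chrom_length) for n in names}
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for i, ni in enumerate(names):
            for nj in names[i + 1 :]:
                r = correlate_maps(binned[ni], binned[nj])
                mat.loc[ni, nj] = mat.loc[nj, ni] = r
        out_corr[res] = mat
    out_share = {}
    binned50 = {n: bin_map(maps[n], 50_000, mask=mask, chrom_length=chrom_length) for n in names}
    for q in q_list:
        hs = {n: call_hotspots(binned50[n], q) for n in names}
        mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
        for i, ni in enumerate(names):
            for nj in names[i + 1 :]:
                s = hotspot_sharing(hs[ni], hs[nj])
                mat.loc[ni, nj] = mat.loc[nj, ni] = s
        out_share[q] = mat
    return {"correlation": out_corr, "sharing": out_share}
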