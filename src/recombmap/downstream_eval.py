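"""Impact of the map choice on local-ancestry calls and imputation accuracy.

Local-ancestry concordance follows the joint-probability construction: at
each site and individual the two haplotype pairings between runs (identity
and swap) are evaluated, the pairing with more label agreements is kept
(ties go to identity), and the outer products of the matched haplotypes'
marginal probability vectors are accumulated into a 4x4 joint matrix whose
normalized trace is the concordance.

Imputation accuracy is the squared Pearson correlation of imputed dosage
with the sequenced genotype per SNP; two maps are compared SNP-matched
with a Wilcoxon signed-rank test and per-MAF-bin summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .mapio import ANCESTRIES, AncestryTrack


def lai_concordance(a: AncestryTrack, b: AncestryTrack, hard_calls: bool = False):
    """4x4 joint ancestry matrix and concordance between two inference runs.

    For each matched haplotype the probability mass
    ``p_a(called_a) * p_b(called_b)`` is accumulated at cell
    ``(called_a, called_b)``, so two identical runs give exactly 100%
    concordance and zero off-diagonal mass.  Returns
    ``(joint, concordance_pct)`` where ``joint`` is a DataFrame in
    PNS/AFR/EAS/EUR order normalized to percent of total mass, and
    concordance is its trace.  ``hard_calls=True`` accumulates unit counts
    at the called labels instead of probability mass.
    """
    if not np.array_equal(a.positions, b.positions) or a.n_ind != b.n_ind:
        raise ValueError("tracks cover different sites or individuals")
    ca, cb = a.calls, b.calls
    # agreements per pairing: identity (h<->h) vs swap (h<->1-h)
    agree_id = (ca[:, :, 0] == cb[:, :, 0]).astype(np.int8) + (ca[:, :, 1] == cb[:, :, 1])
    agree_sw = (ca[:, :, 0] == cb[:, :, 1]).astype(np.int8) + (ca[:, :, 1] == cb[:, :, 0])
    # agreement ties are broken by the larger matched probability mass (a
    # swap-invariant criterion), then toward the identity pairing
    idx = ca[..., None].astype(np.int64)
    pa = np.take_along_axis(a.probs, idx, axis=-1)[..., 0]
    pb = np.take_along_axis(b.probs, cb[..., None].astype(np.int64), axis=-1)[..., 0]
    mass_id = pa[:, :, 0] * pb[:, :, 0] + pa[:, :, 1] * pb[:, :, 1]
    mass_sw = pa[:, :, 0] * pb[:, :, 1] + pa[:, :, 1] * pb[:, :, 0]
    use_swap = (agree_sw > agree_id) | ((agree_sw == agree_id) & (mass_sw > mass_id))
    cb_m = np.where(use_swap[:, :, None], cb[:, :, ::-1], cb)
    joint = np.zeros((4, 4))
    if hard_calls:
        np.add.at(joint, (ca.ravel().astype(np.int64), cb_m.ravel().astype(np.int64)), 1.0)
    else:
        pb_m = np.where(use_swap[:, :, None, None], b.probs[:, :, ::-1, :], b.probs)
        pa_called = np.take_along_axis(a.probs, ca[..., None].astype(np.int64), axis=-1)[..., 0]
        pb_called = np.take_along_axis(pb_m, cb_m[..., None].astype(np.int64), axis=-1)[..., 0]
        w = pa_called * pb_called
        np.add.at(joint, (ca.ravel().astype(np.int64), cb_m.ravel().astype(np.int64)), w.ravel())
    total = joint.sum()
    joint_pct = pd.DataFrame(100.0 * joint / total, index=ANCESTRIES, columns=ANCESTRIES)
    return joint_pct, float(np.trace(joint) / total * 100.0)


def imputation_accuracy(truth: pd.DataFrame, dosage: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP squared Pearson correlation of dosage with sequenced genotype.

    SNPs with zero variance in either vector are dropped; the dropped count
    is reported in the ``n_dropped`` attribute of the result.
    """
    if not truth.index.equals(dosage.index) or not truth.columns.equals(dosage.columns):
        raise ValueError("truth and dosage tables must be aligned")
    t = truth.to_numpy(dtype=float)
    d = dosage.to_numpy(dtype=float)
    st = t.std(axis=1)
    sd = d.std(axis=1)
    ok = (st > 0) & (sd > 0)
    tc = t - t.mean(axis=1, keepdims=True)
    dc = d - d.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc * dc).mean(axis=1) / (st * sd)
    out = pd.DataFrame({"r2": (r**2)[ok]}, index=truth.index[ok])
    out.attrs["n_dropped"] = int((~ok).sum())
    return out


DEFAULT_MAF_BINS = ((0.005, 0.01), (0.01, 0.05), (0.05, 0.50))


def compare_accuracy(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    maf: pd.Series,
    maf_bins=DEFAULT_MAF_BINS,
) -> dict:
    """SNP-matched paired comparison of per-SNP imputation r2 for two maps.

    Wilcoxon signed-rank over all matched SNPs (exact distribution for
    n <= 25 non-zero differences, otherwise normal approximation with
    continuity correction; zero differences dropped, count reported).
    Per-bin medians use the sequenced-truth MAF.
    """
    merged = table_a.join(table_b, lsuffix="_a", rsuffix="_b", how="inner")
    diff = (merged["r2_a"] - merged["r2_b"]).to_numpy()
    nz = diff[diff != 0]
    n_zero = int((diff == 0).sum())
    if nz.size == 0:
        p, stat = 1.0, 0.0
    else:
        mode = "exact" if nz.size <= 25 else "approx"
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=True, mode=mode)
        stat, p = float(res.statistic), float(res.pvalue)
    bins = []
    m = maf.reindex(merged.index)
    for i, (lo, hi) in enumerate(maf_bins):
        upper = (m <= hi) if i == len(maf_bins) - 1 else (m < hi)  # last bin closed
        sel = merged.index[(m >= lo) & upper]
        sub = merged.loc[sel]
        bins.append(
            {
                "maf_lo": lo,
                "maf_hi": hi,
                "n_snps": len(sub),
                "median_r2_a": float(sub["r2_a"].median()) if len(sub) else np.nan,
                "median_r2_b": float(sub["r2_b"].median()) if len(sub) else np.nan,
            }
        )
    return {
        "p_value": p,
        "statistic": stat,
        "n_snps": len(merged),
        "n_zero_diff": n_zero,
        "median_delta": float(np.median(diff)) if diff.size else np.nan,
        "bins": pd.DataFrame(bins),
    }
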