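"""Brute-force reference implementations shared across test modules."""

import numpy as np


def ehh_all_pairs_oracle(haps, core, allele):
    """O(k^2 * m) all-pairs identity comparison for EHH curves."""
    carriers = np.flatnonzero(haps[:, core] == allele)
    k = carriers.size
    npairs = k * (k - 1) / 2
    n_snp = haps.shape[1]
    out = {}
    for direction, rng_ in (("left", range(core - 1, -1, -1)), ("right", range(core + 1, n_snp))):
        curve = [1.0]
        for j in rng_:
            lo, hi = min(j, core), max(j, core)
            ident = 0
            for x in range(k):
                for y in range(x + 1, k):
                    if np.array_equal(
                        haps[carriers[x], lo : hi + 1], haps[carriers[y], lo : hi + 1]
                    ):
                        ident += 1
            curve.append(ident / npairs)
        out[direction] = np.array(curve)
    return out["left"], out["right"]


def brute_force_concordance(a, b):
    """Direct both-pairings counting with probability weights.

    Mirrors the agreement-count / probability-mass / identity tie-break
    hierarchy of the implementation, computed site by site.
    """
    total = diag = 0.0
    for i in range(a.positions.size):
        for j in range(a.n_ind):
            best, best_key = None, None
            for pairing in ((0, 1), (1, 0)):
                agree = sum(
                    a.calls[i, j, h] == b.calls[i, j, pairing[h]] for h in (0, 1)
                )
                mass = sum(
                    a.probs[i, j, h, a.calls[i, j, h]]
                    * b.probs[i, j, pairing[h], b.calls[i, j, pairing[h]]]
                    for h in (0, 1)
                )
                key = (agree, mass)
                if best_key is None or key > best_key:  # identity wins full ties
                    best_key, best = key, pairing
            for h in (0, 1):
                ca, cb = a.calls[i, j, h], b.calls[i, j, best[h]]
                w = a.probs[i, j, h, ca] * b.probs[i, j, best[h], cb]
                total += w
                if ca == cb:
                    diag += w
    return 100.0 * diag / total
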