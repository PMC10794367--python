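#!/usr/bin/env python
"""iHS selection scan: sweep detection and sensitivity to the genetic map.

Three experiments on Wright-Fisher haplotypes:
1. a planted additive sweep (s = 0.05, sampled at 60-90% frequency) scanned
   under the true map — the swept locus should reach the genome-wide top 1%
   of |Z|;
2. the same neutral data scanned under the true map and under a map whose
   rate is inflated x10 across 1 Mb — |Z| shifts concentrate inside the
   misspecified region;
3. a same-map permutation null (disjoint haplotype subsets) for the
   |Z| > 4 vs |Z| < 2 discordance count, the background rate against which
   cross-map discordance is judged.
"""

import argparse
from pathlib import Path

import numpy as np

from recombmap import selection_scan as ss, synthetic_data as sd
from recombmap.mapio import GeneticMap, rescale_region, write_score_track

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    # 1. sweep detection
    gm = GeneticMap.from_rates("1", [0, 60_000_000], [2.0])
    haps, pos, sw = sd.simulate_haplotypes(
        gm, 200, 3000, N_wf=1500, generations=250, seed=args.seed,
        sweep={"position": 30_000_000, "s": 0.05, "start_freq": 0.05, "stop_freq": (0.6, 0.9)},
    )
    z = ss.ihs_scan(ss.HaplotypeMatrix(haps, pos), gm)
    write_score_track(z[["pos", "freq", "ihs", "z"]], OUT / "06_sweep_scan.tsv")
    near = (z["pos"] - int(pos[sw])).abs() <= 100_000
    top = float(np.quantile(z["z"].abs(), 0.99))
    peak = float(z.loc[near, "z"].abs().max())
    print(
        f"Sweep planted at {int(pos[sw]):,} bp (final freq "
        f"{haps[:, sw].mean():.2f}): peak |Z| within 100 kb = {peak:.2f} vs "
        f"genome-wide top-1% cutoff {top:.2f} -> "
        f"{'detected' if peak >= top else 'not detected'}."
    )

    # 2. map misspecification
    L = 30_000_000
    gm2 = GeneticMap.from_rates("1", [0, L], [1.2])
    infl = rescale_region(gm2, 14_500_000, 15_500_000, 10.0)
    haps, pos, _ = sd.simulate_haplotypes(
        gm2, 100, 1200, N_wf=200, generations=100, seed=args.seed + 1
    )
    hm = ss.HaplotypeMatrix(haps, pos)
    z_true = ss.ihs_scan(hm, gm2)
    z_infl = ss.ihs_scan(hm, infl)
    write_score_track(z_true, OUT / "06_scan_true_map.tsv")
    write_score_track(z_infl, OUT / "06_scan_inflated_map.tsv")
    m = z_infl.merge(z_true, on="pos", suffixes=("_infl", "_true"))
    dz = (m["z_infl"] - m["z_true"]).abs()
    inside = (m["pos"] >= 13_500_000) & (m["pos"] < 16_500_000)
    d = ss.cross_map_discordance(z_infl, z_true)
    print(
        f"x10 rate inflation over 1 Mb: mean |Z| shift {dz[inside].mean():.3f} "
        f"inside the region vs {dz[~inside].mean():.3f} outside; "
        f"{d['n_discordant']} SNPs meet the |Z|>4-vs-|Z|<2 discordance rule."
    )

    # 3. same-map permutation null
    null = ss.permutation_null(hm, gm2, n_perm=10, subset_size=50, seed=args.seed + 2)
    print(
        f"Same-map subsample null over {null['counts'].size} permutations: "
        f"mean discordant count {null['mean']:.3f} "
        f"(counts: {np.bincount(null['counts']).tolist()} as 0,1,2,... ).\n"
        f"At this problem size 4-sigma outliers are rare in any single scan, "
        f"so discordance counts on both sides of the comparison are near zero; "
        f"the localized |Z| shift in experiment 2 is the robust signature of "
        f"map misspecification."
    )


if __name__ == "__main__":
    main()
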