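#!/usr/bin/env python
"""Quantify map impact on local-ancestry calls and imputation accuracy.

Local ancestry: a four-way (PNS/AFR/EAS/EUR) Markov mosaic track and a
perturbed re-inference (3% site re-labeling, random haplotype order) are
compared with the joint-probability concordance; the 4x4 matrix mirrors a
two-run agreement table.  Imputation: per-SNP dosage-vs-truth r^2 under
two noise settings, compared SNP-matched by Wilcoxon signed-rank within
MAF bins 0.5-1%, 1-5%, 5-50%.
"""

import argparse
from pathlib import Path

from recombmap import downstream_eval as de, synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    a, b = sd.simulate_ancestry_tracks(50, 400, seed=args.seed, flip_prob=0.03)
    joint, conc = de.lai_concordance(a, b)
    joint.round(3).to_csv(OUT / "05_lai_joint_matrix.tsv", sep="\t")
    print("Joint ancestry matrix (% of probability mass):")
    print(joint.round(2).to_string())
    print(f"Concordance (trace) = {conc:.1f}%\n")

    # same-noise comparison (no planted difference) and a planted gap
    same = sd.simulate_imputation_results(300, 400, seed=args.seed)
    ta = de.imputation_accuracy(same["truth"], same["dosage_a"])
    tb = de.imputation_accuracy(same["truth"], same["dosage_b"])
    out_same = de.compare_accuracy(ta, tb, same["maf"])

    gap = sd.simulate_imputation_results(
        300, 400, seed=args.seed + 1, noise_a=(0.40, 0.30, 0.20), noise_b=(0.50, 0.40, 0.30)
    )
    ga = de.imputation_accuracy(gap["truth"], gap["dosage_a"])
    gb = de.imputation_accuracy(gap["truth"], gap["dosage_b"])
    out_gap = de.compare_accuracy(ga, gb, gap["maf"])

    out_same["bins"].assign(scenario="equal_noise").to_csv(
        OUT / "05_imputation_equal_noise_bins.tsv", sep="\t", index=False
    )
    out_gap["bins"].assign(scenario="planted_gap").to_csv(
        OUT / "05_imputation_planted_gap_bins.tsv", sep="\t", index=False
    )
    print("Imputation accuracy, equal noise (no map difference planted):")
    print(out_same["bins"].to_string(index=False))
    print(f"Wilcoxon signed-rank p = {out_same['p_value']:.3f} -> no detected difference\n")
    print("Imputation accuracy, planted advantage for map A:")
    print(out_gap["bins"].to_string(index=False))
    print(
        f"Wilcoxon signed-rank p = {out_gap['p_value']:.2e}, median r^2 delta "
        f"= {out_gap['median_delta']:.3f} in favour of map A."
    )


if __name__ == "__main__":
    main()
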