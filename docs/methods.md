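# Methods

## Coordinate and unit conventions

All genomic intervals are 0-based half-open internally; genetic-map text
dialects are 1-based on disk and converted only at the I/O boundary, BED is
0-based everywhere. A `GeneticMap` stores physical positions with
cumulative genetic distance; the per-interval rate in cM/Mb is a derived
property, so rate/cumulative consistency is exact by construction.
Cumulative cM starts at 0 at the first map point (whether a released map
anchors at position 0 or at its first SNP is convention; we use the first
point and state it here). Interpolation outside the mapped span clamps to
the terminal cumulative values — zero-rate extrapolation — rather than
extending the terminal rate, so no genetic distance is invented beyond the
observed markers.

Unit chain: ρ per kb ÷ 1000 = ρ per bp; rate in cM/Mb × 10⁻⁸ = r per bp
(recombination probability per bp per meiosis); the slope of ρ/bp on r/bp
is the dimensionless 4Nₑ.

## Map assembly

**Stitching.** Adjacent windows share a declared overlap of SNP positions
(200 by default, matching the windowing convention of LD-based interval
estimation: 4000-SNP windows, 200-SNP overlap). The stitched track takes
the left window's per-interval estimates up to the overlap's boundary SNP
and the right window's from there on; the boundary SNP is the shared SNP
with index ⌊n/2⌋, so odd overlaps resolve one interval toward the left
window (a documented, deterministic tie-break). Mismatched overlap
positions are a hard error naming the first divergent position.

**4Nₑ regression.** ρ and the reference rate are compared over the *same*
physical support: the reference map is first evaluated on the ρ track's SNP
intervals, then both are reduced to bp-weighted means in 5 Mb windows
(masked bp excluded; windows lacking coverage in either track dropped).
The fit is ordinary least squares through the origin, because the model
ρ = 4Nₑ·r has no intercept; an intercept variant is available as an
argument. bp-weighted (rather than per-interval) window means are used
because intervals are unequal in length; the alternative would up-weight
short intervals.

**Rescaling and binning.** r = ρ/4Nₑ per interval; cumulative cM
accumulates from 0 at the first SNP. Binned maps use fixed windows anchored
at coordinate 0 (not the first SNP) so bins are comparable across maps;
per-bin rates are bp-weighted means over unmasked covered bp, bins with no
unmasked coverage — or more than 90% of their span masked — are flagged
missing and excluded pairwise from correlations rather than imputed.

## Landscape comparison

Concordance is the Pearson correlation over jointly non-missing bins (an
error, not NaN, below 3 joint bins or at zero variance). Hotspots are the
top ⌈q·n⌉ non-missing 50 kb bins by mean rate, q ∈ {0.01, 0.10}, computed
genome-wide (per-chromosome percentiles are a supported option); ties at
the threshold break toward the lower bin index. Sharing is |a ∩ b| / |a|,
symmetric because the counts are equal by construction.

## Analysis masks

Marker counts use half-open window membership [s, s+500 kb), s on the
50 kb grid. A window with fewer than 15 markers is flagged and the whole
window span is masked (flagged windows are unioned); masking only the
50 kb step increment is available via an option. The trailing partial
window is judged against a proportionally scaled threshold
⌈15 × width/500 kb⌉ — without this rule every chromosome end under 500 kb
of the boundary would be auto-masked. Applying a mask to a map splits map
intervals at mask boundaries and zeroes the rate inside, so the total
genetic length drops by exactly the masked genetic length and
interpolation away from the mask is unchanged.

## IBD and kinship

Segments on the same haplotype pair and chromosome merge when their
genetic gap (via map interpolation) is strictly below 0.6 cM; merging
chains transitively and lengths are recomputed from the map. The
genotype-discordance condition some merge tools additionally apply ("one
allowed error") requires genotypes and is *not* checked here; merging is
by genetic gap only.

Kinship is φ = Σ segment cM / (4 × genome cM), with segments first trimmed
against the mask and both segment lengths and the genome length measured
on the *same masked map* — φ is therefore invariant to uniform rescaling
of the map. All haplotype-pair segments of a sample pair are summed
without IBD2 deduplication (consistent with the φ formula; fully
duplicated individuals reach φ = 0.5). Degree brackets: φ > 0.354
duplicate/MZ, (0.177, 0.354] 1st, (0.0884, 0.177] 2nd, (0.0442, 0.0884]
3rd, φ ≤ 0.0442 unrelated/distant. Only the 3rd-degree floor is an
empirically used cutoff; the rest follow the powers-of-two convention.
The 0.0442 comparison is strict.

## Local ancestry concordance

At each site and individual the two possible haplotype pairings between
runs (identity and swap) are scored by label agreements; the winning
pairing contributes, for each matched haplotype, the probability mass
p₁(call₁)·p₂(call₂) at cell (call₁, call₂) of a 4×4 joint matrix ordered
PNS, AFR, EAS, EUR. Concordance is the trace over the total mass, in
percent; two identical runs give exactly 100%. Agreement ties are broken
by the larger matched probability mass and then toward the identity
pairing — the mass criterion is what makes the statistic exactly invariant
to per-individual haplotype column order in either input, which a plain
identity tie-break does not achieve with soft probabilities. Every
haplotype-site is weighted equally (per-individual averaging would be the
alternative). A hard-call variant (unit mass at the called labels) is
available.

## Imputation comparison

Per-SNP accuracy is the squared Pearson correlation of imputed dosage with
the sequenced genotype across individuals; SNPs with zero variance on
either side are dropped and counted. Two accuracy tables are compared
SNP-matched by Wilcoxon signed-rank — exact distribution for ≤ 25 non-zero
differences, otherwise the normal approximation with continuity
correction; zero differences are dropped (classical treatment) and
reported, and the all-zero case reports p = 1. Summaries are stratified by
sequencing-based MAF into [0.005, 0.01), [0.01, 0.05), [0.05, 0.50].

## Selection scan

EHH at a flanking SNP is the fraction of carrier-haplotype pairs identical
over the spanned interval; it starts at 1 at the core and is
non-increasing outward. The production kernel maintains a partition of
carriers refined one SNP at a time (numba-compiled, label recompression
each step); the test suite checks it against an all-pairs oracle and an
independent numpy trapezoid integration.

iHH integrates EHH against genetic distance (trapezoid on the cM scale)
outward in both directions, stopping at the first SNP where EHH < 0.05
(that final trapezoid segment is included — a fixed convention that
affects both alleles and both maps identically and cancels in
comparisons). A SNP is skipped when either direction reaches the
chromosome end before the cutoff, crosses a physical gap above 200 kb, or
the site's MAF is below 0.05 — cutoff, gap rule, and MAF floor follow the
reference scan tool's defaults and are all exposed as arguments.
iHS = ln(iHH_ancestral/iHH_derived), so a uniform map rescaling cancels
exactly and swapping allele labels flips the sign.

Normalization z-scores iHS within 50 equal-width derived-allele-frequency
bins (population SD; bins with fewer than 2 SNPs merge into their
neighbor). 50 bins rather than the reference tool's 100 because desk-scale
scans have far fewer SNPs per bin.

**Cross-map discordance and the permutation null.** Discordant SNPs have
|Z| > 4 under one map and |Z| < 2 under the other (both directions
counted; loci clustered at 100 kb for reporting). The null for that count
re-runs the full scan on two disjoint random haplotype subsets under a
*single* map and applies the same rule — between-run variability with no
map difference at all. The exact construction behind published
"same-map permutation" nulls is not standardized; this disjoint-subsample
reading is one defensible interpretation and is flagged as such.

## The synthetic generators: what they emulate, and what they do not

* **Landscape**: two scales of variation — a smooth broad-scale lognormal
  multiplier (5 Mb knots, log-sd 0.5, mean-corrected) over 10 kb gamma
  blocks (shape 2), plus Poisson hotspots (10 per Mb, 2 kb wide, ×12),
  background mean 1.2 cM/Mb (the human sex-averaged genome-wide mean).
  The broad component is what makes replicate-map concordance *rise* with
  bin size, as observed in benchmark comparisons of real maps: with only
  fine-scale structure, signal and noise variance both shrink like
  1/resolution and the concordance-vs-resolution curve is flat. Not
  emulated: PRDM9-driven hotspot turnover, GC-biased rate covariates,
  sex-specific maps.
* **ρ windows**: multiplicative i.i.d. lognormal noise per interval
  (σ = 0.3), drawn independently per window even over shared overlap SNPs,
  emulating independent per-window MCMC runs. ρ ≥ 0 is guaranteed and the
  posterior-mean error of LD-based estimators is roughly multiplicative;
  E[ρ̂] = 4Nₑr·e^{σ²/2}, so the regression slope inherits a ~4.6% upward
  bias at σ = 0.3 — visible in the noisy-recovery numbers and well inside
  their tolerance. Not emulated: autocorrelated MCMC error, block-penalty
  smoothing artifacts.
* **Markers**: Poisson process at 0.485/kb (242.5 markers per 500 kb, an
  array-like density), thinned ×0.01 inside planted gap regions.
* **IBD pairs**: target kinship φ* = 2^{-(m+1)} for m meioses;
  parent–offspring (m = 1) pairs share one full haplotype. For m ≥ 2,
  segment lengths are Exponential(100/m cM) truncated to the chromosome
  and placed uniformly without overlap on a random haplotype pair;
  segments are drawn by renewal stopping against the 4·φ*·L target (the
  final draw is accepted with probability remaining/mean, keeping the
  expected sum on target). The renewal construction concentrates the
  per-pair total around its expectation — by design, so that degree
  recovery is informative about the *pipeline* rather than about
  irreducible segment-count noise; real relatives have substantially
  larger per-pair variance. The default genome for these experiments is a
  22-chromosome, ~3900 cM uniform-rate set with human-like physical
  lengths.
* **Ancestry tracks**: Markov mosaics over PNS/AFR/EAS/EUR with mixing
  proportions (0.50, 0.01, 0.21, 0.28) — a Polynesian-majority four-way
  admixture profile — switch probability 0.02 per site, Dirichlet
  marginals concentrated on the call (weight 30). The perturbed copy
  relabels sites with a given flip probability and randomizes haplotype
  column order. Not emulated: spatially correlated inference errors near
  ancestry switch points.
* **Haplotypes**: discrete Wright–Fisher diploid simulation; crossovers
  per meiosis Poisson(L_cM/100) placed uniformly in genetic distance;
  sites seeded at log-uniform [0.05, 0.95] derived frequencies with no new
  mutation. Sweeps are additive, introduced on copies of a single founder
  haplotype (a hard-sweep configuration — seeding carriers on independent
  backgrounds produces a soft sweep that haplotype statistics rightly
  struggle to see), optionally sampled at the first generation the allele
  enters a target frequency band; allele loss triggers a bounded retry.
  Not emulated: coalescent-scale deep genealogies, recurrent mutation,
  background selection.
* **Imputation**: truth genotypes Binomial(2, MAF) with log-uniform MAF;
  dosages add per-MAF-bin Gaussian noise clipped to [0, 2]. Differences
  between "maps" are planted purely through the noise sigmas.

Because the generators are idealized, green tests demonstrate the
*correctness and calibration of the pipeline* under its stated
assumptions, not the field performance of LD-based map inference on a real
cohort.

## Numerical choices and degenerate inputs

Empty masks are identities; a fully masked map has zero length and
kinship on it is an error (division by zero genome). Empty IBD tables
yield empty estimates. Score normalization of an empty record set returns
an empty frame. All generator determinism flows from
`numpy.random.SeedSequence([seed, stream])` with fixed integer stream
tags, so every artifact is byte-identical under a fixed seed and
independent across stages.

## Known limitations

* The |Z| > 4 vs |Z| < 2 cross-map discordance event is intrinsically a
  large-scan phenomenon: 4-sigma normalized scores essentially require
  10⁴–10⁵ scored SNPs to occur at all, and a localized ×10 rate error can
  change raw iHS by at most ln 10 ≈ 2.3 (iHS is a log-ratio and both iHH
  integrals inflate together), leaving cross-map Z-scores highly
  correlated. Desk-scale scans (10²–10³ scored SNPs) therefore observe
  discordance counts near zero under both the cross-map comparison and
  its permutation null; the robust desk-scale signature of map
  misspecification is the *localized* |Z| shift inside the misspecified
  region, which the suite tests directionally.
* 4Nₑ estimates inherit the multiplicative-noise mean bias e^{σ²/2};
  debiasing would require knowing σ, which real pipelines do not.
* The IBD generator's concentrated segment totals overstate how sharply
  relatedness degrees separate in real data (see above).
* Masks react to marker density only; real analysis masks also consider
  mappability, segmental duplications and array-specific failure modes.
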