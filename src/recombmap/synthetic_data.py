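"""Synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the analyses assume:

* a piecewise-constant recombination landscape with gamma-distributed
  background variation and Poisson-placed hotspots;
* windowed population-scaled estimates rho = 4*Ne*r with multiplicative
  lognormal noise, split into overlapping SNP windows;
* array-like marker grids with planted low-density gaps;
* IBD segments whose expected summed genetic length matches a target
  kinship 2^-(m+1) for a pair separated by m meioses;
* four-ancestry Markov mosaic tracks with Dirichlet marginal probabilities;
* neutral or swept haplotypes from a discrete Wright-Fisher forward
  simulation with map-driven crossovers;
* MAF-stratified imputed dosages with bin-specific noise.

Every generator is a pure function of its arguments and seed: the same
seed yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapio import ANCESTRIES, AncestryTrack, GeneticMap, RhoWindow, RhoWindowSet, validate_ibd
from .mapio import IBD_COLUMNS


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the landscape/marker/rho generators.

    Defaults describe an array-genotyped human autosome at desk scale:
    background 1.2 cM/Mb (the human sex-averaged genome mean), ~10
    hotspots per Mb of width 2 kb carrying a 12x rate elevation, a scaled
    population size 4Ne = 20,000, lognormal noise sigma = 0.3 on rho, and
    0.485 markers/kb (242.5 markers per 500 kb, a MEGA-array-like density).
    """

    seed: int = 0
    genome_length_bp: int = 20_000_000
    background_rate_cM_per_Mb: float = 1.2
    rate_gamma_shape: float = 2.0  # 0 or inf => constant background
    hotspot_density_per_Mb: float = 10.0
    hotspot_width_bp: int = 2_000
    hotspot_multiplier: float = 12.0
    broad_scale_bp: int = 5_000_000
    broad_sigma: float = 0.5
    fourNe: float = 20_000.0
    rho_noise_sigma: float = 0.3
    marker_density_per_kb: float = 0.485
    gap_regions: tuple = ()
    gap_density_factor: float = 0.01

    def __post_init__(self):
        for name in (
            "background_rate_cM_per_Mb",
            "hotspot_density_per_Mb",
            "hotspot_multiplier",
            "fourNe",
            "rho_noise_sigma",
            "marker_density_per_kb",
            "gap_density_factor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["gap_regions"] = [list(g) for g in self.gap_regions]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["gap_regions"] = tuple(tuple(g) for g in d.get("gap_regions", ()))
        return cls(**d)


def _stream_rng(seed, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


_BLOCK_BP = 10_000  # granularity of background-rate variation


def simulate_true_map(cfg: SimConfig, chrom: str = "1") -> GeneticMap:
    """Piecewise-constant recombination landscape with hotspots.

    The landscape has the two scales of variation real maps show: a smooth
    broad-scale component (lognormal multiplier interpolated between knots
    every ``broad_scale_bp``, log-sd ``broad_sigma``, mean-corrected) and a
    fine component drawn per 10 kb block from a gamma distribution with
    mean ``background_rate_cM_per_Mb`` (shape ``rate_gamma_shape``; a
    non-finite or zero shape gives a constant fine background).  Hotspot
    centers follow a Poisson process; within a hotspot the local rate is
    multiplied by ``hotspot_multiplier`` (overlapping hotspots are unioned,
    the multiplier is applied once).
    """
    rng = _stream_rng(cfg.seed, 1)
    L = int(cfg.genome_length_bp)
    n_blocks = -(-L // _BLOCK_BP)
    shape = cfg.rate_gamma_shape
    if shape and np.isfinite(shape) and shape > 0:
        block_rates = rng.gamma(shape, cfg.background_rate_cM_per_Mb / shape, size=n_blocks)
    else:
        block_rates = np.full(n_blocks, cfg.background_rate_cM_per_Mb)
    if cfg.broad_sigma > 0:
        n_knots = max(2, -(-L // int(cfg.broad_scale_bp)) + 1)
        knots_x = np.linspace(0, n_blocks - 1, n_knots)
        knots_y = rng.normal(0.0, cfg.broad_sigma, size=n_knots)
        broad = np.exp(np.interp(np.arange(n_blocks), knots_x, knots_y))
        block_rates = block_rates * broad / np.exp(cfg.broad_sigma**2 / 2)
    n_hot = rng.poisson(cfg.hotspot_density_per_Mb * L / 1e6)
    centers = np.sort(rng.integers(0, L, size=n_hot))
    half = cfg.hotspot_width_bp // 2
    hot = np.stack([np.maximum(centers - half, 0), np.minimum(centers + half, L)], axis=1)
    from . import _intervals

    hot = _intervals.normalize(hot) if n_hot else np.zeros((0, 2), dtype=np.int64)

    edges = np.unique(
        np.concatenate(
            [np.arange(0, L, _BLOCK_BP, dtype=np.int64), [L], hot.ravel().astype(np.int64)]
        )
    )
    edges = edges[(edges >= 0) & (edges <= L)]
    mid = (edges[:-1] + edges[1:]) // 2
    rate = block_rates[np.minimum(mid // _BLOCK_BP, n_blocks - 1)].astype(float)
    if hot.shape[0]:
        in_hot = np.zeros(mid.size, dtype=bool)
        j = np.searchsorted(hot[:, 0], mid, side="right") - 1
        ok = j >= 0
        in_hot[ok] = mid[ok] < hot[j[ok], 1]
        rate[in_hot] *= cfg.hotspot_multiplier
    return GeneticMap.from_rates(chrom, edges, rate)


def simulate_markers(cfg: SimConfig) -> np.ndarray:
    """Poisson-process marker positions, thinned inside planted gap regions."""
    rng = _stream_rng(cfg.seed, 2)
    L = int(cfg.genome_length_bp)
    lam = cfg.marker_density_per_kb / 1000.0
    n = rng.poisson(lam * L)
    pos = np.sort(rng.integers(0, L, size=n))
    keep = np.ones(pos.size, dtype=bool)
    for s, e in cfg.gap_regions:
        inside = (pos >= s) & (pos < e)
        keep[inside] &= rng.random(int(inside.sum())) < cfg.gap_density_factor
    return np.unique(pos[keep])


def true_rho_per_kb(true_map: GeneticMap, positions: np.ndarray, fourNe: float) -> np.ndarray:
    """Noiseless rho/kb on each interval between consecutive positions.

    rho/kb = 4Ne * r_per_bp * 1000, with r_per_bp = cM-per-bp / 100.
    """
    cum = true_map.interpolate_cM(positions)
    d_cm = np.diff(cum)
    d_bp = np.diff(positions).astype(float)
    r_per_bp = d_cm / 100.0 / d_bp
    return fourNe * r_per_bp * 1000.0


def simulate_rho_windows(
    true_map: GeneticMap,
    markers: np.ndarray,
    cfg: SimConfig,
    snps_per_window: int = 4000,
    overlap: int = 200,
) -> RhoWindowSet:
    """Overlapping windows of noisy population-scaled estimates.

    Adjacent windows share exactly ``overlap`` SNP positions, but the
    multiplicative lognormal noise is drawn independently per window, which
    emulates independent per-window MCMC runs over the same sites.
    """
    markers = np.asarray(markers, dtype=np.int64)
    if markers.size <= overlap:
        raise ValueError(f"need more than {overlap} markers, got {markers.size}")
    if overlap >= snps_per_window:
        raise ValueError("overlap must be smaller than the window size")
    rho_true = true_rho_per_kb(true_map, markers, cfg.fourNe)
    step = snps_per_window - overlap
    windows = []
    s = 0
    widx = 0
    while True:
        e = min(s + snps_per_window, markers.size)
        rng = _stream_rng(cfg.seed, 1000 + widx)
        n_int = e - s - 1
        if cfg.rho_noise_sigma > 0:
            eps = rng.lognormal(0.0, cfg.rho_noise_sigma, size=n_int)
        else:
            eps = np.ones(n_int)
        windows.append(
            RhoWindow(
                chrom=true_map.chrom,
                window_index=widx,
                snp_positions=markers[s:e],
                rho_per_kb=rho_true[s : e - 1] * eps,
                n_overlap_left=0 if widx == 0 else overlap,
                n_overlap_right=0 if e == markers.size else overlap,
            )
        )
        if e == markers.size:
            break
        s += step
        widx += 1
    return RhoWindowSet(chrom=true_map.chrom, windows=tuple(windows))


# ---------------------------------------------------------------------------
# IBD pairs


def human_like_genome(
    n_chrom: int = 22, rate_cM_per_Mb: float = 1.2, scale: float = 1.0
) -> list[GeneticMap]:
    """Uniform-rate chromosome set with human-like physical lengths.

    Lengths run linearly from 248 Mb down to 50 Mb (total ~3.3 Gb at
    ``scale=1``), giving ~3900 cM at 1.2 cM/Mb — enough genetic length for
    kinship-degree experiments without per-bp detail.
    """
    lengths = np.linspace(248e6, 50e6, n_chrom) * scale
    return [
        GeneticMap.from_rates(str(i + 1), [0, int(L)], [rate_cM_per_Mb])
        for i, L in enumerate(lengths)
    ]


def simulate_ibd_pairs(
    maps: list[GeneticMap] | GeneticMap,
    n_pairs: int,
    meioses: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IBD segments for pairs separated by ``meioses`` meioses.

    The target kinship is phi* = 2^-(m+1) and the expected summed genetic
    length of segments is 4 * phi* * L_cM.  Parent-offspring (m=1) pairs
    share one full haplotype: one segment spanning each chromosome on a
    single haplotype pair.  For m >= 2, segment genetic lengths are
    Exponential(mean 100/m cM) truncated to the chromosome; segments are
    drawn by renewal stopping against the cM target (the final segment is
    accepted with probability remaining/mean, keeping the expected sum on
    target) and placed uniformly without overlap.  Physical coordinates come
    from inverse interpolation through the map.

    Returns the segment table and a truth table (pair, meioses, phi_expected,
    degree_expected).
    """
    if isinstance(maps, GeneticMap):
        maps = [maps]
    if meioses < 1:
        raise ValueError("meioses must be >= 1")
    rng = _stream_rng(seed, 3)
    L_chrom = np.array([m.total_cM for m in maps])
    L_total = float(L_chrom.sum())
    phi_star = 2.0 ** (-(meioses + 1))
    from .ibd_kinship import classify_degree

    rows = []
    truth = []
    for p in range(n_pairs):
        id1, id2 = f"P{p}_a", f"P{p}_b"
        truth.append((id1, id2, meioses, phi_star, classify_degree(phi_star)))
        if meioses == 1:
            # one fully shared haplotype: whole-chromosome segments on hap pair (1,1)
            for gmap in maps:
                s, e = gmap.span
                rows.append((id1, 1, id2, 1, gmap.chrom, s, e, 50.0, gmap.total_cM))
            continue
        target = 4.0 * phi_star * L_total
        mean_len = 100.0 / meioses
        placed: dict[tuple, list] = {}
        total = 0.0
        for _ in range(10_000):
            remaining = target - total
            if remaining <= 0:
                break
            if remaining < mean_len and rng.random() >= remaining / mean_len:
                break
            ln = rng.exponential(mean_len)
            ci = rng.choice(len(maps), p=L_chrom / L_total)
            gmap = maps[ci]
            Lc = L_chrom[ci]
            ln_c = min(ln, Lc)
            key = (gmap.chrom, int(rng.integers(1, 3)), int(rng.integers(1, 3)))
            ivs = placed.setdefault(key, [])
            ok = False
            for _try in range(50):
                start_cm = rng.uniform(0, Lc - ln_c) if Lc > ln_c else 0.0
                end_cm = start_cm + ln_c
                if all(end_cm <= a or start_cm >= b for a, b in ivs):
                    ok = True
                    break
            if not ok:
                continue
            ivs.append((start_cm, end_cm))
            c0 = float(gmap.cum_cM[0])
            s_bp = int(round(float(gmap.interpolate_bp(c0 + start_cm))))
            e_bp = int(round(float(gmap.interpolate_bp(c0 + end_cm))))
            if e_bp <= s_bp:
                e_bp = s_bp + 1
            rows.append((id1, key[1], id2, key[2], gmap.chrom, s_bp, e_bp, 50.0, ln_c))
            total += ln_c
    seg = pd.DataFrame(rows, columns=IBD_COLUMNS)
    truth_df = pd.DataFrame(
        truth, columns=["id1", "id2", "meioses", "phi_expected", "degree_expected"]
    )
    if len(seg):
        seg = validate_ibd(seg)
    return seg, truth_df


# ---------------------------------------------------------------------------
# Ancestry tracks

# four-way admixture proportions shaped like a Polynesian-ancestry cohort:
# PNS-majority with East Asian and European components and trace African
DEFAULT_ANCESTRY_PROPS = (0.50, 0.01, 0.21, 0.28)


def simulate_ancestry_tracks(
    n_ind: int,
    n_sites: int,
    seed: int,
    k: int = 4,
    switch_prob: float = 0.02,
    flip_prob: float = 0.0,
    prob_concentration: float = 30.0,
    base_props: tuple = DEFAULT_ANCESTRY_PROPS,
    chrom: str = "1",
    genome_length_bp: int = 50_000_000,
) -> tuple[AncestryTrack, AncestryTrack]:
    """A Markov-mosaic ancestry track and a perturbed copy.

    Track A draws each haplotype as a Markov chain over ``k`` labels
    (switches re-draw from ``base_props``).  Track B re-labels each site
    with probability ``flip_prob`` (to a uniformly chosen other label) and
    swaps the two haplotype columns of each individual with probability
    0.5, mimicking a second inference run with arbitrary haplotype order.
    Marginal probability vectors are Dirichlet, concentrated on the called
    label with weight ``prob_concentration``.
    """
    if k != len(ANCESTRIES):
        raise ValueError("k must match the 4-ancestry model")
    rng = _stream_rng(seed, 4)
    props = np.asarray(base_props, dtype=float)
    props = props / props.sum()
    positions = np.sort(rng.choice(genome_length_bp, size=n_sites, replace=False))

    calls_a = np.empty((n_sites, n_ind, 2), dtype=np.int8)
    state = rng.choice(k, size=(n_ind, 2), p=props)
    for i in range(n_sites):
        if i > 0:
            switch = rng.random((n_ind, 2)) < switch_prob
            n_sw = int(switch.sum())
            if n_sw:
                state[switch] = rng.choice(k, size=n_sw, p=props)
        calls_a[i] = state

    calls_b = calls_a.copy()
    if flip_prob > 0:
        flip = rng.random(calls_b.shape) < flip_prob
        shift = rng.integers(1, k, size=int(flip.sum()))
        calls_b[flip] = (calls_b[flip] + shift) % k
    swap = rng.random(n_ind) < 0.5
    calls_b[:, swap, :] = calls_b[:, swap, ::-1]

    def _probs(calls, gen):
        alpha = np.ones((n_sites, n_ind, 2, k))
        np.put_along_axis(alpha, calls[..., None].astype(np.int64), prob_concentration, axis=-1)
        g = gen.standard_gamma(alpha)
        return g / g.sum(axis=-1, keepdims=True)

    probs_a = _probs(calls_a, rng)
    probs_b = _probs(calls_b, rng)
    a = AncestryTrack(chrom, positions, calls_a, probs_a)
    b = AncestryTrack(chrom, positions, calls_b, probs_b)
    return a, b


# ---------------------------------------------------------------------------
# Wright-Fisher haplotypes


def simulate_haplotypes(
    gmap: GeneticMap,
    n_hap: int,
    n_snp: int,
    N_wf: int,
    generations: int,
    seed: int,
    sweep: dict | None = None,
    max_retries: int = 20,
    return_breakpoint_counts: bool = False,
):
    """Forward Wright-Fisher simulation of phased haplotypes.

    ``N_wf`` diploids evolve for ``generations`` discrete generations.
    Crossovers per meiosis are Poisson with mean L_cM/100, placed uniformly
    on the genetic scale and mapped to physical positions through the map.
    Sites are seeded at initialization with log-uniform derived-allele
    frequencies on [0.05, 0.95] and drift thereafter (no new mutations).

    ``sweep`` is ``{"position": bp, "s": float, "start_freq": float}`` for
    an additive selection coefficient on the derived allele at the site
    nearest ``position``.  The swept allele is introduced on copies of a
    single founder haplotype (a hard-sweep configuration: one ancestral
    background rises), so carriers share an extended haplotype.  An
    optional ``"stop_freq": (lo, hi)`` samples the population at the first
    generation the swept allele's frequency enters the band (the usual
    mid-sweep sampling design); ``generations`` then acts as the cap.  If
    the swept allele is lost — or never reaches the band when one is
    requested — the simulation is retried with a fresh stream, up to
    ``max_retries``, then raises.

    Returns ``(haps, positions, sweep_index)`` where ``haps`` is an
    (n_hap, n_snp) 0/1 matrix with 1 = derived.  With
    ``return_breakpoint_counts`` a fourth element carries the per-meiosis
    crossover counts across all generations (for checking the Poisson
    crossover model against the map's genetic length).
    """
    if n_hap > 2 * N_wf:
        raise ValueError("cannot sample more haplotypes than 2*N_wf")
    lo, hi = gmap.span
    for attempt in range(max_retries):
        rng = _stream_rng(seed, 5000 + attempt)
        cand = np.unique(rng.integers(lo, hi, size=2 * n_snp + 16))
        if cand.size < n_snp:
            raise ValueError("n_snp too large for the map's physical span")
        positions = np.sort(rng.choice(cand, size=n_snp, replace=False))
        freqs = np.exp(rng.uniform(np.log(0.05), np.log(0.95), size=n_snp))
        pop = (rng.random((2 * N_wf, n_snp)) < freqs).astype(np.uint8)

        sweep_idx = -1
        s_coef = 0.0
        if sweep is not None:
            sweep_idx = int(np.argmin(np.abs(positions - sweep["position"])))
            s_coef = float(sweep["s"])
            k = int(round(sweep["start_freq"] * 2 * N_wf))
            k = min(max(k, 1), 2 * N_wf - 1)
            carriers = rng.choice(2 * N_wf, size=k, replace=False)
            # hard-sweep configuration: all starting copies share one
            # founder background
            pop[carriers, :] = pop[carriers[0], :]
            pop[:, sweep_idx] = 0
            pop[carriers, sweep_idx] = 1

        cum = gmap.interpolate_cM(positions)
        L_cm = float(cum[-1] - cum[0])
        lost = False
        bp_counts = []
        for _gen in range(generations):
            if sweep_idx >= 0:
                g = pop[0::2, sweep_idx].astype(float) + pop[1::2, sweep_idx].astype(float)
                w = 1.0 + s_coef * g
                pw = w / w.sum()
            else:
                pw = None
            parents = rng.choice(N_wf, size=2 * N_wf, p=pw)
            n_x = rng.poisson(L_cm / 100.0, size=2 * N_wf)
            if return_breakpoint_counts:
                bp_counts.append(n_x.copy())
            which = rng.integers(0, 2, size=2 * N_wf)
            new = np.empty_like(pop)
            for i in range(2 * N_wf):
                h1 = pop[2 * parents[i] + which[i]]
                if n_x[i] == 0:
                    new[i] = h1
                    continue
                h2 = pop[2 * parents[i] + 1 - which[i]]
                cx_cm = rng.uniform(cum[0], cum[-1], size=n_x[i])
                cx_idx = np.searchsorted(cum, np.sort(cx_cm))
                seg = np.zeros(n_snp, dtype=np.uint8)
                for c in cx_idx:
                    seg[c:] ^= 1
                new[i] = np.where(seg == 0, h1, h2)
            pop = new
            if sweep_idx >= 0:
                n_car = int(pop[:, sweep_idx].sum())
                if n_car == 0:
                    lost = True
                    break
                if sweep is not None and "stop_freq" in sweep:
                    f = n_car / (2 * N_wf)
                    if sweep["stop_freq"][0] <= f <= sweep["stop_freq"][1]:
                        break
        if lost:
            continue
        if sweep is not None and "stop_freq" in sweep:
            f = float(pop[:, sweep_idx].sum()) / (2 * N_wf)
            if not (sweep["stop_freq"][0] <= f <= sweep["stop_freq"][1]):
                continue
        sample = rng.choice(2 * N_wf, size=n_hap, replace=False)
        if return_breakpoint_counts:
            return pop[sample], positions, sweep_idx, np.concatenate(bp_counts)
        return pop[sample], positions, sweep_idx
    raise RuntimeError(f"sweep allele lost in all {max_retries} attempts")


# ---------------------------------------------------------------------------
# Imputation results

DEFAULT_MAF_BINS = ((0.005, 0.01), (0.01, 0.05), (0.05, 0.50))


def simulate_imputation_results(
    n_snp: int,
    n_ind: int,
    seed: int,
    maf_bins: tuple = DEFAULT_MAF_BINS,
    noise_a: tuple = (0.45, 0.35, 0.25),
    noise_b: tuple = (0.45, 0.35, 0.25),
) -> dict:
    """Sequenced-truth genotypes and two imputed-dosage sets.

    True genotypes are Binomial(2, MAF) with MAF log-uniform over the full
    bin range; dosages add Gaussian noise with a per-bin sigma (clipped to
    [0, 2]).  Passing different ``noise_a``/``noise_b`` plants a recoverable
    accuracy difference between the two "maps"; equal tuples plant none.
    """
    rng = _stream_rng(seed, 6)
    lo = maf_bins[0][0]
    hi = maf_bins[-1][1]
    maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_snp))
    maf = np.minimum(maf, hi - 1e-9)
    truth = rng.binomial(2, maf[:, None], size=(n_snp, n_ind)).astype(float)

    edges = np.array([b[0] for b in maf_bins] + [maf_bins[-1][1]])
    bin_idx = np.clip(np.searchsorted(edges, maf, side="right") - 1, 0, len(maf_bins) - 1)

    def _dosage(sigmas, tag):
        g = _stream_rng(seed, tag)
        sd = np.asarray(sigmas, dtype=float)[bin_idx]
        return np.clip(truth + g.normal(0, sd[:, None], size=truth.shape), 0.0, 2.0)

    snp_ids = [f"snp{i}" for i in range(n_snp)]
    ind_ids = [f"ind{j}" for j in range(n_ind)]
    return {
        "maf": pd.Series(maf, index=snp_ids, name="maf"),
        "truth": pd.DataFrame(truth, index=snp_ids, columns=ind_ids),
        "dosage_a": pd.DataFrame(_dosage(noise_a, 7), index=snp_ids, columns=ind_ids),
        "dosage_b": pd.DataFrame(_dosage(noise_b, 8), index=snp_ids, columns=ind_ids),
    }
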