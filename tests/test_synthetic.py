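"""Generator contracts: determinism, degenerate limits, and distributional
self-consistency checked by direct sampling."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from recombmap import synthetic_data as sd
from recombmap.mapio import GeneticMap


def test_simconfig_json_roundtrip():
    cfg = sd.SimConfig(seed=9, gap_regions=((100, 200), (5_000, 9_000)), rho_noise_sigma=0.4)
    assert sd.SimConfig.from_json(cfg.to_json()) == cfg


class TestTrueMap:
    def test_determinism(self):
        cfg = sd.SimConfig(seed=42, genome_length_bp=2_000_000)
        m1, m2 = sd.simulate_true_map(cfg), sd.simulate_true_map(cfg)
        assert m1.allclose(m2)
        assert np.array_equal(m1.positions, m2.positions)

    def test_degenerate_config_gives_uniform_map(self):
        cfg = sd.SimConfig(
            seed=1,
            genome_length_bp=2_000_000,
            hotspot_density_per_Mb=0.0,
            rate_gamma_shape=0.0,
            broad_sigma=0.0,
        )
        m = sd.simulate_true_map(cfg)
        assert np.allclose(m.rate_cM_per_Mb, cfg.background_rate_cM_per_Mb)

    def test_total_length_is_rate_times_distance(self):
        cfg = sd.SimConfig(
            seed=1,
            genome_length_bp=100_000_000,
            background_rate_cM_per_Mb=1.0,
            hotspot_density_per_Mb=0.0,
            rate_gamma_shape=0.0,
            broad_sigma=0.0,
        )
        assert sd.simulate_true_map(cfg).total_cM == pytest.approx(100.0)

    def test_hotspots_raise_total_length(self):
        base = sd.SimConfig(seed=3, genome_length_bp=5_000_000, hotspot_density_per_Mb=0.0)
        hot = dataclasses.replace(base, hotspot_density_per_Mb=20.0)
        assert sd.simulate_true_map(hot).total_cM > sd.simulate_true_map(base).total_cM


class TestRhoWindows:
    def test_noiseless_equals_scaled_truth(self):
        cfg = sd.SimConfig(seed=5, genome_length_bp=4_000_000, rho_noise_sigma=0.0)
        tm = sd.simulate_true_map(cfg)
        mk = sd.simulate_markers(cfg)
        ws = sd.simulate_rho_windows(tm, mk, cfg, snps_per_window=500, overlap=100)
        expect = sd.true_rho_per_kb(tm, mk, cfg.fourNe)
        for w in ws:
            i0 = np.searchsorted(mk, w.snp_positions[0])
            assert np.allclose(w.rho_per_kb, expect[i0 : i0 + w.rho_per_kb.size])

    def test_overlap_positions_shared_verbatim(self):
        cfg = sd.SimConfig(seed=5, genome_length_bp=4_000_000)
        tm = sd.simulate_true_map(cfg)
        mk = sd.simulate_markers(cfg)
        ws = list(sd.simulate_rho_windows(tm, mk, cfg, snps_per_window=500, overlap=100))
        for left, right in zip(ws, ws[1:]):
            assert np.array_equal(left.snp_positions[-100:], right.snp_positions[:100])

    def test_too_few_markers_raises(self, uniform_map):
        cfg = sd.SimConfig(seed=5)
        with pytest.raises(ValueError, match="markers"):
            sd.simulate_rho_windows(uniform_map, np.arange(50), cfg, overlap=200)

    def test_lognormal_mean_identity(self):
        # E[rho]/ (4Ne * r) = exp(sigma^2/2), checked by direct sampling
        sigma = 0.4
        cfg = sd.SimConfig(
            seed=7,
            genome_length_bp=100_000_000,
            rho_noise_sigma=sigma,
            marker_density_per_kb=1.2,
            hotspot_density_per_Mb=0.0,
            rate_gamma_shape=0.0,
        )
        tm = sd.simulate_true_map(cfg)
        mk = sd.simulate_markers(cfg)
        ws = sd.simulate_rho_windows(tm, mk, cfg)
        truth = sd.true_rho_per_kb(tm, mk, cfg.fourNe)
        ratios = []
        for w in ws:
            i0 = np.searchsorted(mk, w.snp_positions[0])
            ratios.append(w.rho_per_kb / truth[i0 : i0 + w.rho_per_kb.size])
        ratios = np.concatenate(ratios)
        assert ratios.size > 1e5
        expected = np.exp(sigma**2 / 2)
        se = ratios.std() / np.sqrt(ratios.size)
        assert abs(ratios.mean() - expected) < 4 * se


def test_markers_thinned_in_gap_regions():
    gap = (5_000_000, 7_000_000)
    cfg = sd.SimConfig(seed=9, genome_length_bp=20_000_000, gap_regions=(gap,))
    mk = sd.simulate_markers(cfg)
    in_gap = int(((mk >= gap[0]) & (mk < gap[1])).sum())
    density_out = (mk.size - in_gap) / 18_000
    density_in = in_gap / 2_000
    assert density_in < 0.05 * density_out


class TestIBDPairs:
    def test_parent_offspring_spans_each_chromosome(self):
        maps = sd.human_like_genome(n_chrom=3)
        seg, truth = sd.simulate_ibd_pairs(maps, 2, meioses=1, seed=1)
        total = sum(m.total_cM for m in maps)
        for pair, grp in seg.groupby("id1"):
            assert len(grp) == 3
            assert grp["length_cM"].sum() == pytest.approx(total)
        assert (truth["degree_expected"] == "1st").all()

    def test_expected_sum_matches_kinship_target(self):
        # law of large numbers: mean summed cM -> 4 * phi* * L
        maps = sd.human_like_genome()
        L = sum(m.total_cM for m in maps)
        for m_meioses in (2, 4):
            seg, _ = sd.simulate_ibd_pairs(maps, 400, meioses=m_meioses, seed=11)
            per_pair = seg.groupby("id1")["length_cM"].sum()
            per_pair = per_pair.reindex([f"P{i}_a" for i in range(400)]).fillna(0.0)
            target = 4 * 2.0 ** -(m_meioses + 1) * L
            assert abs(per_pair.mean() - target) / target < 0.10

    def test_mean_phi_for_third_degree_generator(self):
        # m=4 pairs: phi-hat within 15% of 2^-5
        maps = sd.human_like_genome()
        L = sum(m.total_cM for m in maps)
        seg, _ = sd.simulate_ibd_pairs(maps, 500, meioses=4, seed=13)
        phi = seg.groupby("id1")["length_cM"].sum() / (4 * L)
        phi = phi.reindex([f"P{i}_a" for i in range(500)]).fillna(0.0)
        assert abs(phi.mean() - 2**-5) / 2**-5 < 0.15

    def test_sharing_vanishes_for_many_meioses(self):
        maps = sd.human_like_genome(n_chrom=4)
        L = sum(m.total_cM for m in maps)
        seg, _ = sd.simulate_ibd_pairs(maps, 200, meioses=14, seed=15)
        mean_sum = seg["length_cM"].sum() / 200
        assert mean_sum < 0.01 * L


class TestAncestryTracks:
    def test_no_flip_tracks_agree_up_to_haplotype_order(self):
        a, b = sd.simulate_ancestry_tracks(6, 40, seed=17, flip_prob=0.0)
        for j in range(a.n_ind):
            direct = np.array_equal(a.calls[:, j, :], b.calls[:, j, :])
            swapped = np.array_equal(a.calls[:, j, :], b.calls[:, j, ::-1])
            assert direct or swapped

    def test_determinism(self):
        a1, b1 = sd.simulate_ancestry_tracks(4, 20, seed=19, flip_prob=0.1)
        a2, b2 = sd.simulate_ancestry_tracks(4, 20, seed=19, flip_prob=0.1)
        assert np.array_equal(a1.calls, a2.calls)
        assert np.allclose(b1.probs, b2.probs)

    def test_probability_mass_concentrates_on_call(self):
        a, _ = sd.simulate_ancestry_tracks(5, 30, seed=21, prob_concentration=50.0)
        called_p = np.take_along_axis(a.probs, a.calls[..., None].astype(np.int64), -1)
        assert called_p.mean() > 0.85


class TestWrightFisher:
    def test_zero_map_gives_no_recombinants(self):
        # without recombination only whole-haplotype copying occurs, so every
        # sampled haplotype must be a verbatim copy of a founder haplotype
        gm = GeneticMap.from_rates("1", [0, 1_000_000], [0.0])
        haps, _, _ = sd.simulate_haplotypes(gm, 20, 80, N_wf=30, generations=15, seed=23)
        # the founder pool is recovered by sampling all 2N haplotypes at
        # generation 0 with the same seed (identical init stream)
        founders = sd.simulate_haplotypes(gm, 60, 80, N_wf=30, generations=0, seed=23)[0]
        founder_types = {tuple(h) for h in founders}
        assert all(tuple(h) in founder_types for h in haps)

    def test_determinism(self):
        gm = GeneticMap.from_rates("1", [0, 2_000_000], [1.0])
        h1 = sd.simulate_haplotypes(gm, 10, 50, N_wf=20, generations=10, seed=25)[0]
        h2 = sd.simulate_haplotypes(gm, 10, 50, N_wf=20, generations=10, seed=25)[0]
        assert np.array_equal(h1, h2)

    def test_neutral_sweep_site_is_martingale(self):
        # s=0: mean final frequency over replicates within 3 SE of start
        gm = GeneticMap.from_rates("1", [0, 1_000_000], [1.0])
        start = 0.5
        finals = []
        for rep in range(200):
            haps, _, sw = sd.simulate_haplotypes(
                gm, 40, 30, N_wf=40, generations=15, seed=10_000 + rep,
                sweep={"position": 500_000, "s": 0.0, "start_freq": start},
            )
            finals.append(haps[:, sw].mean())
        finals = np.asarray(finals)
        se = finals.std() / np.sqrt(finals.size)
        assert abs(finals.mean() - start) < 3 * se

    def test_breakpoints_per_meiosis_poisson(self):
        # chi-square GOF of crossover counts against Poisson(L_cM / 100)
        gm = GeneticMap.from_rates("1", [0, 50_000_000], [2.0])  # 100 cM -> mean 1
        out = sd.simulate_haplotypes(
            gm, 10, 60, N_wf=50, generations=20, seed=27, return_breakpoint_counts=True
        )
        counts = out[3]
        assert counts.size == 2000
        mean = 1.0
        kmax = 5
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        probs = np.array([stats.poisson.pmf(k, mean) for k in range(kmax)] + [0.0])
        probs[kmax] = 1 - probs.sum()
        res = stats.chisquare(obs, probs * counts.size)
        assert res.pvalue > 0.01

    def test_sweep_lost_raises_after_retries(self):
        gm = GeneticMap.from_rates("1", [0, 1_000_000], [1.0])
        with pytest.raises(RuntimeError, match="lost"):
            # strong negative selection forces loss every attempt
            sd.simulate_haplotypes(
                gm, 10, 30, N_wf=30, generations=60, seed=29, max_retries=3,
                sweep={"position": 500_000, "s": -0.9, "start_freq": 0.02},
            )


class TestImputationGenerator:
    def test_structure_and_determinism(self):
        r1 = sd.simulate_imputation_results(50, 30, seed=31)
        r2 = sd.simulate_imputation_results(50, 30, seed=31)
        assert r1["truth"].equals(r2["truth"])
        assert r1["dosage_a"].equals(r2["dosage_a"])
        assert ((r1["maf"] >= 0.005) & (r1["maf"] <= 0.5)).all()
        assert r1["truth"].isin([0.0, 1.0, 2.0]).all().all()
        assert ((r1["dosage_a"] >= 0) & (r1["dosage_a"] <= 2)).all().all()

    def test_equal_noise_tuples_give_different_noise_draws(self):
        r = sd.simulate_imputation_results(50, 30, seed=31)
        assert not r["dosage_a"].equals(r["dosage_b"])
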