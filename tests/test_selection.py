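"""EHH/iHS computation, normalization, and map-sensitivity machinery."""

import numpy as np
import pandas as pd
import pytest

from recombmap import selection_scan as ss, synthetic_data as sd
from recombmap.mapio import GeneticMap, rescale_region
from _oracles import ehh_all_pairs_oracle


@pytest.fixture(scope="module")
def wf_data():
    gm = GeneticMap.from_rates("1", [0, 30_000_000], [1.2])
    haps, pos, _ = sd.simulate_haplotypes(gm, 60, 1200, N_wf=120, generations=80, seed=101)
    return gm, ss.HaplotypeMatrix(haps, pos)


class TestEHH:
    def test_identical_carriers_keep_ehh_one(self):
        haps = np.zeros((10, 20), dtype=np.uint8)
        haps[:4, 10] = 1  # 4 identical derived carriers
        hm = ss.HaplotypeMatrix(haps, np.arange(20) * 100)
        left, right = ss.ehh(hm, 10, 1)
        assert np.allclose(left, 1.0) and np.allclose(right, 1.0)

    def test_immediate_even_split_drops_to_combinatorial_value(self):
        k = 6
        haps = np.zeros((k, 3), dtype=np.uint8)
        haps[:, 1] = 1  # all carry the core allele
        haps[: k // 2, 2] = 1  # split into two equal groups at the next SNP
        hm = ss.HaplotypeMatrix(haps, np.array([0, 100, 200]))
        _, right = ss.ehh(hm, 1, 1)
        expected = 2 * (k // 2) * (k // 2 - 1) / 2 / (k * (k - 1) / 2)
        assert right[1] == pytest.approx(expected)

    def test_non_increasing_outward(self, rng):
        haps = (rng.random((20, 50)) < 0.5).astype(np.uint8)
        haps[:, 25] = np.repeat([0, 1], 10)
        hm = ss.HaplotypeMatrix(haps, np.arange(50) * 1000)
        left, right = ss.ehh(hm, 25, 1)
        assert np.all(np.diff(left) <= 1e-12) and np.all(np.diff(right) <= 1e-12)

    def test_matches_all_pairs_oracle(self, rng):
        haps = (rng.random((20, 50)) < 0.4).astype(np.uint8)
        haps[:, 25] = (rng.random(20) < 0.5).astype(np.uint8)
        if haps[:, 25].sum() < 2 or haps[:, 25].sum() > 18:
            haps[:5, 25] = 1
            haps[5:, 25] = 0
        hm = ss.HaplotypeMatrix(haps, np.arange(50) * 1000)
        for allele in (0, 1):
            left, right = ss.ehh(hm, 25, allele)
            o_left, o_right = ehh_all_pairs_oracle(haps, 25, allele)
            assert np.allclose(left, o_left)
            assert np.allclose(right, o_right)


class TestIHS:
    def test_map_scale_cancels_in_log_ratio(self, wf_data):
        gm, hm = wf_data
        r1 = ss.ihs_unstandardized(hm, gm)
        r2 = ss.ihs_unstandardized(hm, gm.scaled(2.0))
        merged = r1.merge(r2, on="pos", suffixes=("_1", "_2"))
        assert len(merged) > 100
        assert np.allclose(merged["ihh_derived_2"], 2 * merged["ihh_derived_1"], rtol=1e-9)
        assert np.allclose(merged["ihs_2"], merged["ihs_1"], rtol=1e-9, atol=1e-12)

    def test_antisymmetric_under_allele_label_swap(self, wf_data):
        gm, hm = wf_data
        r1 = ss.ihs_unstandardized(hm, gm)
        flipped = ss.HaplotypeMatrix(1 - hm.haps, hm.positions)
        r2 = ss.ihs_unstandardized(flipped, gm)
        merged = r1.merge(r2, on="pos", suffixes=("_1", "_2"))
        assert np.allclose(merged["ihs_2"], -merged["ihs_1"], rtol=1e-9, atol=1e-12)
        assert np.allclose(merged["freq_2"], 1 - merged["freq_1"])

    def test_matches_trapezoid_integration_oracle(self, wf_data):
        # independent numpy path: EHH curves + literal trapezoid accumulation
        # with the same truncation semantics as the scan kernel
        gm, hm = wf_data
        rec = ss.ihs_unstandardized(hm, gm)
        cm = gm.interpolate_cM(hm.positions)
        pos_index = {int(p): i for i, p in enumerate(hm.positions)}
        for _, row in rec.iloc[:: max(1, len(rec) // 15)].iterrows():
            s = pos_index[int(row.pos)]
            ihh = {}
            for allele in (1, 0):
                left, right = ss.ehh(hm, s, allele)
                area = 0.0
                for curve, step in ((left, -1), (right, +1)):
                    prev_e, j = 1.0, s
                    for e in curve[1:]:
                        jn = j + step
                        area += abs(cm[jn] - cm[j]) * (prev_e + e) / 2
                        prev_e, j = e, jn
                        if e < 0.05:
                            break
                ihh[allele] = area
            assert row.ihs == pytest.approx(np.log(ihh[0] / ihh[1]), rel=1e-9)

    def test_map_not_covering_positions_raises(self, wf_data):
        _, hm = wf_data
        small = GeneticMap.from_rates("1", [0, 1000], [1.0])
        with pytest.raises(ValueError, match="cover"):
            ss.ihs_unstandardized(hm, small)


class TestNormalize:
    def test_single_bin_zscore_identity(self, rng):
        rec = pd.DataFrame(
            {"pos": np.arange(100), "freq": np.full(100, 0.5), "ihs": rng.normal(0, 2, 100)}
        )
        out = ss.normalize_ihs(rec, n_freq_bins=1)
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z"].std(ddof=0) == pytest.approx(1.0)

    def test_location_invariance(self, rng):
        rec = pd.DataFrame(
            {"pos": np.arange(200), "freq": rng.uniform(0.05, 0.95, 200), "ihs": rng.normal(size=200)}
        )
        shifted = rec.assign(ihs=rec["ihs"] + 7.5)
        pd.testing.assert_series_equal(
            ss.normalize_ihs(rec)["z"], ss.normalize_ihs(shifted)["z"]
        )

    def test_sparse_bins_merged(self):
        rec = pd.DataFrame(
            {"pos": [1, 2, 3], "freq": [0.02, 0.5, 0.51], "ihs": [1.0, 2.0, 3.0]}
        )
        out = ss.normalize_ihs(rec, n_freq_bins=50)
        assert np.isfinite(out["z"]).all()


class TestDiscordance:
    def test_identical_scans_give_empty_sets(self, rng):
        z = pd.DataFrame({"pos": np.arange(50) * 1000, "z": rng.normal(size=50), "ihs": 0.0, "freq": 0.5})
        out = ss.cross_map_discordance(z, z)
        assert out["n_discordant"] == 0

    def test_threshold_semantics(self):
        za = pd.DataFrame({"pos": [100], "z": [4.5]})
        zb = pd.DataFrame({"pos": [100], "z": [1.0]})
        out = ss.cross_map_discordance(za, zb)
        assert list(out["a_not_b"]) == [100]
        assert list(out["b_not_a"]) == []

    def test_matches_filter_oracle(self, rng):
        n = 500
        za = pd.DataFrame({"pos": np.arange(n) * 1000, "z": rng.normal(0, 2, n)})
        zb = pd.DataFrame({"pos": np.arange(n) * 1000, "z": rng.normal(0, 2, n)})
        out = ss.cross_map_discordance(za, zb)
        oracle_a = {
            int(p)
            for p, x, y in zip(za["pos"], za["z"], zb["z"])
            if abs(x) > 4.0 and abs(y) < 2.0
        }
        assert set(out["a_not_b"]) == oracle_a

    def test_loci_clustering(self):
        za = pd.DataFrame({"pos": [0, 50_000, 500_000], "z": [5.0, 5.0, 5.0]})
        zb = pd.DataFrame({"pos": [0, 50_000, 500_000], "z": [0.0, 0.0, 0.0]})
        out = ss.cross_map_discordance(za, zb)
        assert len(out["loci_a_not_b"]) == 2


class TestPermutationNull:
    def test_zero_permutations_empty(self, wf_data):
        gm, hm = wf_data
        out = ss.permutation_null(hm, gm, n_perm=0, subset_size=20, seed=1)
        assert out["counts"].size == 0

    def test_forced_identical_subsets_always_zero(self, wf_data):
        gm, hm = wf_data
        out = ss.permutation_null(
            hm, gm, n_perm=2, subset_size=25, seed=2, force_identical=True
        )
        assert np.all(out["counts"] == 0)


class TestMapSensitivity:
    def test_z_changes_concentrate_inside_inflated_region(self):
        # the central directional claim at desk scale: a x10 rate error over
        # 1 Mb moves normalized scores inside/near that region more than
        # elsewhere (paired across seeds)
        L = 30_000_000
        gm = GeneticMap.from_rates("1", [0, L], [1.2])
        infl = rescale_region(gm, 14_500_000, 15_500_000, 10.0)
        diffs = []
        for seed in range(5):
            haps, pos, _ = sd.simulate_haplotypes(
                gm, 80, 1500, N_wf=150, generations=80, seed=300 + seed
            )
            hm = ss.HaplotypeMatrix(haps, pos)
            za = ss.ihs_scan(hm, infl)
            zb = ss.ihs_scan(hm, gm)
            m = za.merge(zb, on="pos", suffixes=("_a", "_b"))
            dz = (m["z_a"] - m["z_b"]).abs()
            near = (m["pos"] >= 13_500_000) & (m["pos"] < 16_500_000)
            if near.sum() >= 10 and (~near).sum() >= 10:
                diffs.append(dz[near].mean() - dz[~near].mean())
        assert np.mean(diffs) > 0

    def test_sweep_lands_in_genome_wide_top_scores(self):
        # planted additive sweep (s = 0.05, sampled at frequency 0.6-0.9):
        # the strongest |Z| within 100 kb of the swept site is in the
        # genome-wide top 1% in at least 80% of 25 replicates
        L = 60_000_000
        gm = GeneticMap.from_rates("1", [0, L], [2.0])
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            haps, pos, sw = sd.simulate_haplotypes(
                gm, 200, 3000, N_wf=1500, generations=250, seed=seed,
                sweep={"position": 30_000_000, "s": 0.05, "start_freq": 0.05,
                       "stop_freq": (0.6, 0.9)},
            )
            hm = ss.HaplotypeMatrix(haps, pos)
            z = ss.ihs_scan(hm, gm)
            near = (z["pos"] - int(pos[sw])).abs() <= 100_000
            if not near.any():
                continue
            top = np.quantile(z["z"].abs(), 0.99)
            if z.loc[near, "z"].abs().max() >= top:
                hits += 1
        assert hits / n_seeds >= 0.8
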