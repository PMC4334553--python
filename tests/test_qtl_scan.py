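"""Haley-Knott scans, permutation thresholds and interval construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drivekit.qtl_scan import (
    LOD_CAP,
    MarkerMatrix,
    build_intervals,
    grid_intervals,
    hk_scan_binary,
    hk_scan_quantitative,
    permutation_threshold,
    sum_intensity_phenotype,
)
from drivekit.synthetic_data import SimConfig, haldane_r, simulate_backcross


def simple_markers(codes):
    codes = np.asarray(codes, dtype=float)
    n_ind, n_loc = codes.shape
    return MarkerMatrix(
        individuals=tuple(f"i{k}" for k in range(n_ind)),
        loci=tuple(("chr1", float(j)) for j in range(n_loc)),
        codes=codes,
    )


def default_map(n_markers=40, spacing_cM=2.5, chrom="chr1"):
    return [(chrom, j * 1e6, j * spacing_cM) for j in range(n_markers)]


class TestBuildIntervals:
    def test_two_breakpoints(self):
        ivs = build_intervals({"chr1": [[10.0], [20.0]]})
        assert ivs == [("chr1", -np.inf, 10.0), ("chr1", 10.0, 20.0),
                       ("chr1", 20.0, np.inf)]

    def test_no_recombinants_single_interval(self):
        ivs = build_intervals({"chr1": [[], []]}, bounds={"chr1": (0.0, 100.0)})
        assert ivs == [("chr1", 0.0, 100.0)]

    def test_within_interval_constancy_brute_force(self):
        rng = np.random.default_rng(17)
        bps = {"chr1": [sorted(rng.uniform(0, 100, rng.integers(0, 5)).tolist())
                        for _ in range(8)]}
        ivs = build_intervals(bps, bounds={"chr1": (0.0, 100.0)})
        # an individual's genotype can only change at its own breakpoints;
        # verify no individual breakpoint falls strictly inside an interval
        for _, lo, hi in ivs:
            for ind in bps["chr1"]:
                for b in ind:
                    assert not (lo < b < hi)
        # and the intervals tile the chromosome
        assert ivs[0][1] == 0.0 and ivs[-1][2] == 100.0
        for a, b in zip(ivs[:-1], ivs[1:]):
            assert a[2] == b[1]

    def test_grid_intervals_cover_genome(self):
        ivs = grid_intervals({"chr1": (0.0, 60.0), "chr2": (0.0, 40.0)}, n_total=10)
        assert sum(1 for c, _, _ in ivs if c == "chr1") == 6
        assert sum(1 for c, _, _ in ivs if c == "chr2") == 4


class TestQuantitativeScan:
    def test_matches_explicit_likelihood_ratio_oracle(self):
        # brute-force LOD from explicit normal log-likelihoods at the MLE
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            codes = rng.integers(0, 2, size=(n, 4)).astype(float)
            y = rng.normal(size=n) + codes[:, 1]
            scan = hk_scan_quantitative(simple_markers(codes), y)
            for j in range(4):
                g = codes[:, j]
                if np.unique(g).size < 2:
                    continue
                def ll(resid):
                    s2 = np.mean(resid**2)
                    return -0.5 * n * (np.log(2 * np.pi * s2) + 1)
                r0 = y - y.mean()
                r1 = y.copy()
                for v in (0.0, 1.0):
                    r1[g == v] = y[g == v] - y[g == v].mean()
                lod_oracle = (ll(r1) - ll(r0)) / np.log(10)
                assert scan.lod[j] == pytest.approx(lod_oracle, abs=1e-6)

    def test_null_scan_small_lod(self):
        cfg = SimConfig(seed=71)
        markers, y = simulate_backcross(cfg, default_map(), 200, qtl_index=None)
        scan = hk_scan_quantitative(markers, y)
        assert scan.lod.max() < 4.0
        assert np.median(scan.lod) < 1.0

    def test_perfect_fit_capped_and_flagged(self):
        codes = np.array([[0], [0], [1], [1], [0], [1]], dtype=float)
        y = codes[:, 0].copy()
        scan = hk_scan_quantitative(simple_markers(codes), y)
        assert scan.lod[0] == LOD_CAP
        assert "perfect_fit" in scan.flags[0]

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 2, size=(60, 5)).astype(float)
        y = rng.normal(size=60) + 0.8 * codes[:, 2]
        a = hk_scan_quantitative(simple_markers(codes), y)
        b = hk_scan_quantitative(simple_markers(codes), 3.5 * y - 11.0)
        assert np.allclose(a.lod, b.lod)

    def test_peak_near_truth_in_simulated_backcross(self):
        # a backcross of the size used for array sum-intensity mapping:
        # 330 individuals, 1-s.d. additive effect
        qtl = 20
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = SimConfig(seed=seed)
            markers, y = simulate_backcross(
                cfg, default_map(), 330, qtl_index=qtl, effect_size=1.0
            )
            scan = hk_scan_quantitative(markers, y)
            if abs(int(np.argmax(scan.lod)) - qtl) <= 2:
                hits += 1
        assert hits >= round(0.95 * n_rep)

    def test_constant_phenotype_all_zero(self):
        codes = np.array([[0], [1]] * 5, dtype=float)
        scan = hk_scan_quantitative(simple_markers(codes), np.ones(10))
        assert scan.lod[0] == 0.0


class TestBinaryScan:
    def test_single_class_rejected(self):
        codes = np.array([[0], [1]] * 5, dtype=float)
        with pytest.raises(ValueError):
            hk_scan_binary(simple_markers(codes), np.ones(10))

    def test_null_distribution_matches_half_chi2_scaling(self):
        # under the null, 2 ln(10) LOD ~ chi-square(1); check the median
        rng = np.random.default_rng(55)
        lods = []
        for _ in range(300):
            codes = rng.integers(0, 2, size=(60, 1)).astype(float)
            y = rng.integers(0, 2, size=60).astype(float)
            if np.unique(y).size < 2:
                continue
            lods.append(hk_scan_binary(simple_markers(codes), y).lod[0])
        observed_median = np.median(lods)
        expected_median = stats.chi2.ppf(0.5, df=1) / (2 * np.log(10))
        assert observed_median == pytest.approx(expected_median, abs=0.05)

    def test_lod_ranking_matches_likelihood_ratio_statistic(self):
        rng = np.random.default_rng(21)
        codes = rng.integers(0, 2, size=(40, 6)).astype(float)
        y = (rng.random(40) < 0.3 + 0.4 * codes[:, 3]).astype(float)
        scan = hk_scan_binary(simple_markers(codes), y)
        g2 = []
        for j in range(6):
            table = np.zeros((2, 2))
            for gi, yi in zip(codes[:, j], y):
                table[int(gi), int(yi)] += 1
            res = stats.chi2_contingency(table + 1e-300, correction=False,
                                         lambda_="log-likelihood")
            g2.append(res.statistic)
        assert list(np.argsort(scan.lod)) == list(np.argsort(g2))

    def test_perfect_concordance_unique_peak(self):
        # the small-pedigree design: 25 dams, presence of distortion
        # perfectly concordant with one locus
        cfg = SimConfig(seed=101)
        marker_map = [(c, j * 5e6, j * 20.0) for c in ("chr1", "chr2", "chr3")
                      for j in range(8)]
        markers, _ = simulate_backcross(cfg, marker_map, 25)
        qtl = 10  # chr2, third marker
        y = markers.codes[:, qtl].copy()
        scan = hk_scan_binary(markers, y)
        thr = permutation_threshold(markers, y, scan="binary", alpha=0.01,
                                    n_perm=500, seed=7)
        assert int(np.argmax(scan.lod)) == qtl
        assert scan.lod[qtl] > thr
        off_chrom = [scan.lod[j] for j, (c, _) in enumerate(markers.loci)
                     if c != "chr2"]
        assert max(off_chrom) < thr
        assert "separation" in scan.flags[qtl]


class TestPermutationThreshold:
    def test_constant_phenotype_zero_threshold(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 2, size=(30, 5)).astype(float)
        thr = permutation_threshold(simple_markers(codes), np.full(30, 2.0),
                                    alpha=0.05, n_perm=100, seed=3)
        assert thr == 0.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 2, size=(50, 8)).astype(float)
        y = rng.normal(size=50)
        m = simple_markers(codes)
        t1 = permutation_threshold(m, y, alpha=0.05, n_perm=200, seed=42)
        t2 = permutation_threshold(m, y, alpha=0.05, n_perm=200, seed=42)
        assert t1 == t2
        t3 = permutation_threshold(m, y, alpha=0.05, n_perm=200, seed=43)
        assert t1 != t3  # different seed explores different permutations

    def test_type_one_error_calibrated(self):
        # null datasets: genome-wide max should exceed the alpha=0.1
        # threshold in roughly 10% of replicates
        exceed = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = SimConfig(seed=seed + 500)
            markers, y = simulate_backcross(cfg, default_map(n_markers=15), 60)
            thr = permutation_threshold(markers, y, alpha=0.1, n_perm=150,
                                        seed=seed)
            if hk_scan_quantitative(markers, y).lod.max() > thr:
                exceed += 1
        se = np.sqrt(0.1 * 0.9 / n_rep)
        assert abs(exceed / n_rep - 0.1) < 3 * se + 1 / n_rep

    def test_invalid_alpha(self):
        codes = np.zeros((10, 2))
        with pytest.raises(ValueError):
            permutation_threshold(simple_markers(codes), np.ones(10), alpha=1.5,
                                  n_perm=100, seed=1)


class TestSumIntensity:
    def test_single_probe_passthrough(self):
        df = pd.DataFrame({"s1": [1.5], "s2": [2.5]}, index=["p1"])
        ph = sum_intensity_phenotype(df, ["p1"])
        assert ph["s1"] == 1.5 and ph["s2"] == 2.5

    def test_copy_number_classes_separate(self):
        from drivekit.synthetic_data import simulate_array

        cfg = SimConfig(seed=61)
        samples = [(f"s{i}", cn) for i, cn in enumerate([1, 2, 34] * 10)]
        probes = simulate_array(cfg, samples, n_probes=3)
        ph = sum_intensity_phenotype(probes, list(probes.index))
        by_cn = {cn: [] for cn in (1, 2, 34)}
        for (sid, cn) in samples:
            by_cn[cn].append(ph[sid])
        assert max(by_cn[1]) < min(by_cn[2]) < max(by_cn[2]) < min(by_cn[34])

    def test_missing_probe_diagnostics(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        with pytest.raises(KeyError, match="p9"):
            sum_intensity_phenotype(df, ["p1", "p9"])

    def test_zero_intensities(self):
        df = pd.DataFrame({"s1": [0.0, 0.0]}, index=["p1", "p2"])
        assert sum_intensity_phenotype(df, ["p1", "p2"])["s1"] == 0.0


class TestHaldane:
    def test_recombination_fraction_between_adjacent_markers(self):
        cfg = SimConfig(seed=81)
        markers, _ = simulate_backcross(cfg, default_map(n_markers=2, spacing_cM=20.0),
                                        4000)
        flips = np.mean(markers.codes[:, 0] != markers.codes[:, 1])
        assert flips == pytest.approx(haldane_r(20.0), abs=0.02)

    def test_haldane_limits(self):
        assert haldane_r(0.0) == 0.0
        assert haldane_r(1e6) == pytest.approx(0.5)
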