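"""Weir-Cockerham theta, the neutral envelope and outlier detection."""

import numpy as np
import pandas as pd
import pytest

from popadapt import (
    GenotypeMatrix, conditional_envelope, detect_outliers, hotspot_test,
    island_null_simulate, pairwise_ld_r2, weir_cockerham_fst,
)


def gm_from_counts(genotype_counts):
    """Panel from per-pop genotype counts [(n_AA, n_Aa, n_aa), ...]."""
    rows = []
    pops = []
    for k, (n0, n1, n2) in enumerate(genotype_counts):
        rows += [0.0] * n0 + [1.0] * n1 + [2.0] * n2
        pops += [k] * (n0 + n1 + n2)
    dosage = np.array(rows)[:, None]
    g = GenotypeMatrix(dosage=dosage, loci=pd.DataFrame({"id": ["L0"]}),
                       samples=[f"s{i}" for i in range(len(rows))])
    return g, np.array(pops)


def wc_oracle(n, p, h):
    """Literal 1984 textbook evaluation for one locus, r populations."""
    n = np.asarray(n, float); p = np.asarray(p, float); h = np.asarray(h, float)
    r = len(n)
    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / n.sum()
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                     / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


class TestWeirCockerham:
    def test_identical_pops_theta_nonpositive_small(self):
        g, pops = gm_from_counts([(5, 4, 1), (5, 4, 1)])
        t = weir_cockerham_fst(g, pops).table
        assert t["fst"].iloc[0] <= 0.0
        assert abs(t["fst"].iloc[0]) < 0.1

    def test_fixed_difference_near_one(self):
        g, pops = gm_from_counts([(50, 0, 0), (0, 0, 50)])
        t = weir_cockerham_fst(g, pops).table
        assert t["fst"].iloc[0] > 0.95

    def test_matches_textbook_oracle(self):
        """HWE counts for 6/20 vs 14/20 alternate alleles, 10 diploids."""
        # p=0.3: (4.9, 4.2, 0.9) -> integers (5,4,1); p=0.7: (1,4,5)
        g, pops = gm_from_counts([(5, 4, 1), (1, 4, 5)])
        t = weir_cockerham_fst(g, pops).table
        expected = wc_oracle([10, 10], [0.3, 0.7], [0.4, 0.4])
        assert t["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_random_panels_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = [tuple(rng.integers(1, 8, 3)) for _ in range(3)]
            g, pops = gm_from_counts(counts)
            t = weir_cockerham_fst(g, pops).table
            n = [sum(c) for c in counts]
            p = [(c[1] + 2 * c[2]) / (2 * sum(c)) for c in counts]
            h = [c[1] / sum(c) for c in counts]
            if not (0 < np.average(p, weights=n) < 1):
                continue
            assert t["fst"].iloc[0] == pytest.approx(
                wc_oracle(n, p, h), abs=1e-12)

    def test_monomorphic_locus_nan(self):
        g, pops = gm_from_counts([(10, 0, 0), (10, 0, 0)])
        t = weir_cockerham_fst(g, pops).table
        assert np.isnan(t["fst"].iloc[0])


class TestIslandNull:
    def test_pilot_calibration_within_5pct(self):
        pairs = island_null_simulate(0.0078, d=4, n_sims=30_000, seed=1)
        mean = pairs["a"].sum() / (pairs["a"] + pairs["b"] + pairs["c"]).sum()
        assert abs(mean - 0.0078) <= 0.05 * 0.0078

    def test_determinism(self):
        p1 = island_null_simulate(0.02, n_sims=2000, seed=9)
        p2 = island_null_simulate(0.02, n_sims=2000, seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            island_null_simulate(0.0, n_sims=100, seed=0)
        with pytest.raises(ValueError):
            island_null_simulate(0.1, d=10, n_demes=4, n_sims=100, seed=0)


@pytest.fixture(scope="module")
def pairs():
    return island_null_simulate(0.01, d=4, n_sims=40_000, seed=3)


class TestEnvelope:
    def test_noncrossing_and_ordering(self, pairs):
        env = conditional_envelope(pairs, ci=0.99)
        assert np.all(env.lower < env.upper)
        assert np.all(np.diff(env.he_grid) > 0)

    def test_neutral_exceedance_near_1pct(self, pairs):
        env = conditional_envelope(pairs, ci=0.99)
        fresh = island_null_simulate(0.01, d=4, n_sims=10_000, seed=4)
        lo, hi = env.bounds(fresh["he"].to_numpy())
        out = ((fresh["fst"].to_numpy() > hi)
               | (fresh["fst"].to_numpy() < lo)).mean()
        # binomial 99.9% interval around 0.01 at n = 10,000
        assert 0.006 < out < 0.015

    def test_ci_domain_validated(self, pairs):
        with pytest.raises(ValueError):
            conditional_envelope(pairs, ci=0.4)


class TestDetectOutliers:
    def test_planted_outliers_recovered(self, island_panel):
        """2 planted high-F_ST loci flagged against a 0.01 background."""
        hits = 0
        for seed in range(5):
            from popadapt import SimConfig, sim_island_genotypes
            cfg = SimConfig(n_pops=4, n_per_pop=100, n_loci=98, n_clinal_loci=0,
                            target_fst=0.01, seed=300 + seed)
            g, truth = sim_island_genotypes(cfg)
            # plant two strongly diverged loci (deme freqs 0.18 / 0.82
            # realize theta ~ 0.5 among four demes)
            rng = np.random.default_rng(400 + seed)
            p_hi = np.where(truth.cluster_labels < 2, 0.18, 0.82)
            planted = rng.binomial(2, p_hi[:, None], size=(len(p_hi), 2))
            dosage = np.hstack([g.dosage, planted.astype(float)])
            loci = pd.DataFrame({"id": [f"L{j}" for j in range(100)]})
            gm = GenotypeMatrix(dosage=dosage, loci=loci, samples=g.samples)
            obs = weir_cockerham_fst(gm, truth.cluster_labels)
            res = detect_outliers(obs, d=4, n_sims=8000, seed=seed)
            high = set(res["flags"].loc[res["flags"]["flag"] == "high", "id"])
            if high == {"L98", "L99"} and res["mean_neutral_fst"] < 0.03:
                hits += 1
        assert hits >= 4

    def test_identical_fst_fixed_point(self):
        # constant-theta table: trimming cannot change the mean
        tab = pd.DataFrame({
            "id": [f"L{j}" for j in range(50)],
            "fst": 0.01, "he": np.linspace(0.1, 0.5, 50),
            "a": 0.01, "b": 0.5, "c": 0.49,
        })
        from popadapt.outliers import FstTable
        obs = FstTable(table=tab, populations=[0, 1, 2, 3])
        res = detect_outliers(obs, d=4, n_sims=5000, seed=0)
        assert res["mean_neutral_fst"] == pytest.approx(
            obs.multilocus_fst, rel=1e-9)

    def test_locus_order_invariance(self, island_panel):
        g, truth, cfg = island_panel
        obs = weir_cockerham_fst(g, truth.cluster_labels)
        res1 = detect_outliers(obs, d=4, n_sims=4000, seed=2)
        perm = np.random.default_rng(0).permutation(g.n_loci)
        g2 = g.subset_loci(perm)
        obs2 = weir_cockerham_fst(g2, truth.cluster_labels)
        res2 = detect_outliers(obs2, d=4, n_sims=4000, seed=2)
        f1 = res1["flags"].set_index("id")["flag"]
        f2 = res2["flags"].set_index("id")["flag"]
        assert f1.sort_index().equals(f2.sort_index())

    def test_trimming_monotone(self, island_panel):
        g, truth, cfg = island_panel
        obs = weir_cockerham_fst(g, truth.cluster_labels)
        res = detect_outliers(obs, d=4, n_sims=4000, seed=5)
        flags = res["flags"]
        if (flags["flag"] == "high").any() and not (flags["flag"] == "low").any():
            assert res["mean_neutral_fst"] <= obs.multilocus_fst + 1e-12


class TestHotspot:
    def test_all_on_one_chromosome(self):
        chroms = ["chr7"] * 118
        res = hotspot_test(chroms, n_chromosomes=19, n_perm=1000, seed=0)
        expected_chi2 = (118 - 118 / 19) ** 2 / (118 / 19) + 18 * (118 / 19)
        assert res["chi2"] == pytest.approx(expected_chi2, rel=1e-12)
        assert res["df"] == 18
        assert "chr7" in res["hotspots"]

    def test_uniform_counts_no_hotspot(self):
        chroms = [f"chr{i}" for i in range(19) for _ in range(6)]
        res = hotspot_test(chroms, n_chromosomes=19, n_perm=500, seed=1)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["hotspots"] == []

    def test_df_rule_and_empty_error(self):
        res = hotspot_test(["c1", "c2"], n_chromosomes=19, n_perm=100, seed=0)
        assert res["df"] == 18
        with pytest.raises(ValueError):
            hotspot_test([], n_chromosomes=19)


class TestPairwiseLd:
    def test_self_and_duplicate_r2_one(self, tiny_genotypes):
        g = tiny_genotypes
        dosage = np.hstack([g.dosage, g.dosage[:, [0]]])
        loci = pd.DataFrame({"id": [f"L{j}" for j in range(5)]})
        g2 = GenotypeMatrix(dosage=dosage, loci=loci, samples=g.samples)
        r2 = pairwise_ld_r2(g2, [0, 4])
        assert r2.iloc[0, 0] == pytest.approx(1.0)
        assert r2.iloc[0, 1] == pytest.approx(1.0)

    def test_constructed_correlation_recovered(self):
        rng = np.random.default_rng(12)
        n = 4000
        z = rng.normal(size=n)
        x1 = (z + rng.normal(size=n) * np.sqrt(3)) > 0   # corr(x1*, x2*) = 0.5
        x2 = (z + rng.normal(size=n) * np.sqrt(3)) > 0
        dosage = np.column_stack([x1, x2]).astype(float)
        g = GenotypeMatrix(dosage=dosage,
                           loci=pd.DataFrame({"id": ["a", "b"]}),
                           samples=[f"s{i}" for i in range(n)])
        r2 = pairwise_ld_r2(g, [0, 1])
        rho = np.corrcoef(x1, x2)[0, 1]
        assert r2.iloc[0, 1] == pytest.approx(rho**2, abs=1e-9)

    def test_monomorphic_locus_nan(self):
        dosage = np.column_stack([np.ones(6), np.arange(6) % 3]).astype(float)
        g = GenotypeMatrix(dosage=dosage,
                           loci=pd.DataFrame({"id": ["m", "v"]}),
                           samples=[f"s{i}" for i in range(6)])
        r2 = pairwise_ld_r2(g, [0, 1])
        assert np.isnan(r2.loc["m", "v"])
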