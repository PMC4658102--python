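"""Climate clustering, the SAM logistic scan and frequency regressions."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from popadapt import (
    GenotypeMatrix, cluster_freq_regression, kmedoids_ch, sam_scan,
)
from popadapt.glm import logistic_tests


def climate_blobs(seed=0, k=3, n_per=40, sep=6.0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(k, 3)) * sep
    X = np.vstack([centers[i] + rng.normal(size=(n_per, 3)) * 0.5
                   for i in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    clim = pd.DataFrame(X, columns=["MAT", "NFFD", "MAP"])
    return clim, labels


class TestKmedoids:
    def test_separated_blobs_recover_k_and_labels(self):
        clim, truth = climate_blobs(seed=1, k=3)
        ca = kmedoids_ch(clim, range(2, 7), seed=0)
        assert ca.K == 3
        assert adjusted_rand_score(truth, ca.labels) == 1.0
        assert max(ca.ch_by_k, key=ca.ch_by_k.get) == 3

    def test_duplication_invariance(self):
        clim, _ = climate_blobs(seed=2, k=3, n_per=15)
        ca1 = kmedoids_ch(clim, [3], seed=0)
        doubled = pd.concat([clim, clim], ignore_index=True)
        ca2 = kmedoids_ch(doubled, [3], seed=0)
        med1 = set(map(tuple, clim.iloc[ca1.medoid_indices].to_numpy()))
        med2 = set(map(tuple, doubled.iloc[ca2.medoid_indices].to_numpy()))
        assert med1 == med2

    def test_affine_rescaling_invariance(self):
        clim, _ = climate_blobs(seed=3, k=3)
        ca1 = kmedoids_ch(clim, range(2, 6), seed=0)
        scaled = clim.copy()
        scaled["MAP"] = scaled["MAP"] * 250.0 + 800.0
        ca2 = kmedoids_ch(scaled, range(2, 6), seed=0)
        assert ca2.K == ca1.K
        np.testing.assert_array_equal(ca1.labels, ca2.labels)

    def test_k_bounds_validated(self):
        clim, _ = climate_blobs(seed=4, k=2, n_per=10)
        with pytest.raises(ValueError):
            kmedoids_ch(clim, [15], seed=0)
        with pytest.raises(ValueError):
            kmedoids_ch(clim, [], seed=0)


def make_panel(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        dosage=dosage, loci=pd.DataFrame({"id": [f"L{j}" for j in range(m)]}),
        samples=[f"s{i}" for i in range(n)])


class TestSamScan:
    def test_bonferroni_threshold_bookkeeping(self):
        rng = np.random.default_rng(0)
        g = make_panel(rng.binomial(2, 0.4, size=(60, 10)))
        env = pd.DataFrame({"MAT": rng.normal(size=60),
                            "NFFD": rng.normal(size=60),
                            "MAP": rng.normal(size=60)})
        res = sam_scan(g, env, alpha=0.05, env_mode="individual")
        assert res.attrs["n_models"] == 30
        assert res.attrs["threshold"] == pytest.approx(0.05 / 30)
        assert len(res) == 30

    def test_strong_dependence_passes_all_three(self):
        rng = np.random.default_rng(1)
        n = 400
        mat = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(3.0 * (mat - mat.mean()) / mat.std())))
        dosage = rng.binomial(2, p)[:, None].astype(float)
        extra = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        g = make_panel(np.hstack([dosage, extra]))
        env = pd.DataFrame({"MAT": mat, "NFFD": rng.normal(size=n),
                            "MAP": rng.normal(size=n)})
        res = sam_scan(g, env, alpha=0.05, env_mode="individual")
        hit = res[(res["id"] == "L0") & (res["variable"] == "MAT")]
        assert bool(hit["pass"].iloc[0])

    def test_permuted_env_family_wise_error(self):
        """With env shuffled against genotypes, few scans reject anything."""
        rng = np.random.default_rng(2)
        rejections = 0
        n_scans = 25
        for s in range(n_scans):
            g = make_panel(rng.binomial(2, 0.4, size=(80, 8)))
            env = pd.DataFrame({"MAT": rng.permutation(np.linspace(-2, 2, 80)),
                                "NFFD": rng.normal(size=80),
                                "MAP": rng.normal(size=80)})
            res = sam_scan(g, env, alpha=0.05, env_mode="individual")
            rejections += int(res["pass"].any())
        assert rejections <= max(3, int(0.05 * n_scans) + 2)

    def test_lr_statistic_matches_likelihood_oracle(self):
        """LR equals 2(l_full - l_null) from an independent evaluation."""
        rng = np.random.default_rng(3)
        n = 120
        z = rng.normal(size=n)
        dosage = rng.binomial(2, 1 / (1 + np.exp(-0.8 * z))).astype(float)
        r = logistic_tests(dosage, z)
        # independent evaluation via statsmodels GLM binomial
        import statsmodels.api as sm
        X = sm.add_constant(z)
        fit = sm.GLM(np.column_stack([dosage, 2 - dosage]), X,
                     family=sm.families.Binomial()).fit()
        null = sm.GLM(np.column_stack([dosage, 2 - dosage]),
                      np.ones((n, 1)),
                      family=sm.families.Binomial()).fit()
        lr_sm = 2 * (fit.llf - null.llf)
        assert r["lr_stat"] == pytest.approx(lr_sm, abs=1e-8)
        assert r["slope"] == pytest.approx(fit.params[1], abs=1e-6)

    def test_cluster_mean_mode(self):
        rng = np.random.default_rng(4)
        g = make_panel(rng.binomial(2, 0.4, size=(40, 3)))
        env = pd.DataFrame({"MAT": rng.normal(size=40),
                            "NFFD": rng.normal(size=40),
                            "MAP": rng.normal(size=40)})
        clusters = np.repeat([1, 2, 3, 4], 10)
        res = sam_scan(g, env, clusters=clusters, env_mode="cluster-mean")
        assert len(res) == 9
        with pytest.raises(ValueError, match="cluster"):
            sam_scan(g, env, env_mode="cluster-mean")


class TestFreqRegression:
    def test_exact_linear_relation_r2_one(self):
        freqs = np.sin(0.3 + 0.05 * np.array([4.0, 6.0, 8.0, 10.0])) ** 2
        cols = []
        for f in freqs:
            # realize the frequency exactly from 50 alleles in 25 diploids
            k = int(round(f * 50))
            alleles = np.r_[np.ones(k), np.zeros(50 - k)]
            cols.append(alleles[:50:2] + alleles[1:50:2])
        dosage = np.concatenate(cols)[:, None]
        g = make_panel(dosage)
        clusters = np.repeat([1, 2, 3, 4], 25)
        realized = np.array([dosage[clusters == c].mean() / 2
                             for c in (1, 2, 3, 4)])
        # regress on the realized-arcsine-exact predictor to hit R^2 = 1
        x_exact = np.arcsin(np.sqrt(realized))
        means = pd.DataFrame({"MAT": x_exact}, index=[1, 2, 3, 4])
        res = cluster_freq_regression(g, clusters, means)
        assert res["r2"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_frequencies_r2_zero(self):
        block = np.array([0, 1, 2, 1, 1] * 5, dtype=float)   # one cluster
        dosage = np.tile(block, 4)[:, None]                  # identical in all
        g = make_panel(dosage)
        clusters = np.repeat([1, 2, 3, 4], 25)
        means = pd.DataFrame({"MAT": [4.0, 6.0, 8.0, 10.0]},
                             index=[1, 2, 3, 4])
        res = cluster_freq_regression(g, clusters, means)
        assert res["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_frequency_temperature_high_r2(self):
        rng = np.random.default_rng(5)
        freqs = [0.2, 0.4, 0.6, 0.8]
        cols = [rng.binomial(2, f, size=200) for f in freqs]
        g = make_panel(np.concatenate(cols)[:, None].astype(float))
        clusters = np.repeat([1, 2, 3, 4], 200)
        means = pd.DataFrame({"MAT": [4.0, 6.0, 8.0, 10.0]},
                             index=[1, 2, 3, 4])
        res = cluster_freq_regression(g, clusters, means)
        assert res["r2"].iloc[0] > 0.9

    def test_cluster_relabel_invariance_and_boundary_flag(self):
        rng = np.random.default_rng(6)
        dosage = np.concatenate([
            np.zeros(20), rng.binomial(2, 0.5, 20).astype(float),
            rng.binomial(2, 0.6, 20).astype(float), np.full(20, 2.0),
        ])[:, None]
        g = make_panel(dosage)
        clusters = np.repeat([1, 2, 3, 4], 20)
        means = pd.DataFrame({"MAT": [4.0, 6.0, 8.0, 10.0]},
                             index=[1, 2, 3, 4])
        res = cluster_freq_regression(g, clusters, means)
        assert bool(res["boundary"].iloc[0])
        relabeled = np.select([clusters == c for c in (1, 2, 3, 4)],
                              [10, 20, 30, 40])
        means2 = means.set_axis([10, 20, 30, 40])
        res2 = cluster_freq_regression(g, relabeled, means2)
        assert res2["r2"].iloc[0] == pytest.approx(res["r2"].iloc[0])

    def test_too_few_clusters_rejected(self):
        g = make_panel(np.array([[0.0], [2.0]]))
        with pytest.raises(ValueError):
            cluster_freq_regression(g, [1, 2],
                                    pd.DataFrame({"MAT": [1, 2]}, index=[1, 2]))
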