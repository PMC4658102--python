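"""REML fitter, collapsed clonal models and the Q_ST / h2 / P_ST ratios."""

import numpy as np
import pytest
from scipy.optimize import minimize

from popadapt import (
    MixedModelSpec, QstEstimate, VarianceComponents, animal_model_spec,
    broad_qst, clone_model_spec, cluster_design, h2_pst, narrow_qst,
    reml_fit, restricted_loglik,
)
from popadapt.mixedmodel import _expand_grm


def direct_reml_maximum(spec, k, starts=None):
    """Independent oracle: direct maximization of the restricted likelihood
    over log-variances via Nelder-Mead from several starts."""
    parts = spec.covariance_parts()

    def neg(logs):
        return -restricted_loglik(spec, np.exp(logs), parts)

    vary = np.var(spec.y, ddof=1)
    if starts is None:
        starts = [np.log(np.full(k, vary / k)),
                  np.log(np.full(k, vary)),
                  np.log(np.geomspace(0.1, 1, k) * vary)]
    best = None
    for s0 in starts:
        r = minimize(neg, s0, method="Nelder-Mead",
                     options=dict(xatol=1e-11, fatol=1e-13, maxiter=8000))
        if best is None or r.fun < best.fun:
            best = r
    return -best.fun, np.exp(best.x)


class TestRemlClosedForms:
    def test_residual_only_equals_ols_mse(self):
        rng = np.random.default_rng(0)
        n = 35
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [2.0, -1.0] + rng.normal(size=n) * 1.3
        vc = reml_fit(MixedModelSpec(y=y, X=X, random_terms=[]))
        bh = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ bh) ** 2))
        assert vc["residual"] == pytest.approx(rss / (n - 2), rel=1e-8)
        assert vc.converged

    def test_balanced_oneway_matches_anova(self):
        """Interior optimum equals the (MSB-MSW)/m, MSW closed forms."""
        rng = np.random.default_rng(1)
        g, m = 10, 10
        lab = np.repeat(np.arange(g), m)
        y = 5 + rng.normal(scale=np.sqrt(2.0), size=g)[lab] \
            + rng.normal(size=g * m)
        Z = cluster_design(lab)
        vc = reml_fit(MixedModelSpec(y=y, X=np.ones((g * m, 1)),
                                     random_terms=[("grp", Z, None)]),
                      tol=1e-12, grad_tol=1e-9)
        ybar = y.reshape(g, m).mean(axis=1)
        msb = m * np.sum((ybar - y.mean()) ** 2) / (g - 1)
        msw = np.sum((y.reshape(g, m) - ybar[:, None]) ** 2) / (g * (m - 1))
        assert vc["grp"] == pytest.approx((msb - msw) / m, rel=1e-5)
        assert vc["residual"] == pytest.approx(msw, rel=1e-5)


class TestRemlOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_loglik_matches_direct_maximization(self, seed):
        """Restricted log-likelihood at the fit within 1e-6 of a direct
        maximization on random toy specs (n <= 30)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(18, 31))
        lab = rng.integers(0, 3, n)
        B = rng.normal(size=(n, 6))
        K = B @ B.T / 6 + 0.1 * np.eye(n)
        Zp = cluster_design(lab)
        L = np.linalg.cholesky(K)
        y = (1.0 + Zp @ rng.normal(scale=0.8, size=Zp.shape[1])
             + L @ rng.normal(size=n) * 0.6 + rng.normal(size=n))
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), random_terms=[
            ("cluster", Zp, None), ("additive", np.eye(n), K)])
        vc = reml_fit(spec)
        ll_direct, _ = direct_reml_maximum(spec, 3)
        assert vc.loglik_restricted >= ll_direct - 1e-6

    def test_nonidentifiable_identity_grm_flagged(self):
        """G = I without clones confounds additive and residual terms."""
        rng = np.random.default_rng(9)
        n = 24
        lab = rng.integers(0, 3, n)
        spec = MixedModelSpec(
            y=rng.normal(size=n), X=np.ones((n, 1)),
            random_terms=[("cluster", cluster_design(lab), None),
                          ("additive", np.eye(n), np.eye(n))])
        vc = reml_fit(spec)
        assert not vc.identifiable


class TestCollapsedReplication:
    def test_collapsed_equals_dense_fit(self):
        """Genotype-mean collapse reproduces the dense replicated fit."""
        rng = np.random.default_rng(5)
        ng, r = 30, 3
        B = rng.normal(size=(ng, 10))
        K = B @ B.T / 10 + 0.05 * np.eye(ng)
        lab = rng.integers(0, 4, ng)
        gi = np.repeat(np.arange(ng), r)
        L = np.linalg.cholesky(K)
        y = (3 + rng.normal(scale=0.6, size=4)[lab][gi]
             + (L @ rng.normal(size=ng))[gi] * 0.7
             + rng.normal(size=ng * r) * 0.9)
        Zp = cluster_design(lab[gi])
        Za, KK = _expand_grm(K, gi)
        dense = MixedModelSpec(y=y, X=np.ones((ng * r, 1)), random_terms=[
            ("cluster", Zp, None), ("additive", Za, KK)])
        vc_dense = reml_fit(dense)
        vc_coll = reml_fit(animal_model_spec(y, lab[gi], K, genotype_index=gi))
        for name in ("cluster", "additive", "residual"):
            assert vc_coll[name] == pytest.approx(vc_dense[name],
                                                  rel=1e-4, abs=1e-8)

    def test_single_ramet_clone_model_rejected(self):
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="confounded"):
            clone_model_spec(y, np.repeat([0, 1], 5), np.arange(10))


class TestQstRatios:
    def make_vc(self, sp, sa, cov=None):
        est = {"cluster": sp, "additive": sa, "residual": 1.0}
        cov = np.eye(3) * 1e-4 if cov is None else cov
        return VarianceComponents(estimates=est, cov=cov, converged=True,
                                  n_iter=5, loglik_restricted=0.0)

    @pytest.mark.parametrize("sp,sa,expected", [
        (0.0, 0.5, 0.0),
        (1.0, 0.5, 0.5),      # sp = 2 sa is the symmetry point
        (0.2, 0.4, 0.2),
    ])
    def test_narrow_qst_values(self, sp, sa, expected):
        q = narrow_qst(self.make_vc(sp, sa), d=4)
        assert q.value == pytest.approx(expected, abs=1e-12)
        assert q.d == 4

    def test_narrow_qst_degenerate(self):
        q = narrow_qst(self.make_vc(0.0, 0.0), d=4)
        assert q.degenerate and np.isnan(q.value)

    def test_narrow_qst_monotone(self):
        qs = [narrow_qst(self.make_vc(sp, 0.4), d=4).value
              for sp in (0.1, 0.2, 0.4)]
        assert qs == sorted(qs)
        qa = [narrow_qst(self.make_vc(0.2, sa), d=4).value
              for sa in (0.1, 0.2, 0.4)]
        assert qa == sorted(qa, reverse=True)

    def test_scale_invariance_of_ratios(self):
        """Rescaling y by c leaves Q_ST, h2 and P_ST unchanged."""
        rng = np.random.default_rng(11)
        ng, r = 40, 2
        B = rng.normal(size=(ng, 12))
        K = B @ B.T / 12 + 0.1 * np.eye(ng)
        lab = rng.integers(0, 3, ng)
        gi = np.repeat(np.arange(ng), r)
        L = np.linalg.cholesky(K)
        y = (rng.normal(scale=0.5, size=3)[lab][gi]
             + (L @ rng.normal(size=ng))[gi] + rng.normal(size=ng * r))
        res = {}
        for c in (1.0, 7.3):
            vc = reml_fit(animal_model_spec(c * y, lab[gi], K, genotype_index=gi))
            h2, pst, _, _ = h2_pst(c * y, K, lab[gi], genotype_index=gi)
            res[c] = (narrow_qst(vc, d=3).value, h2.value, pst.value)
        assert res[1.0] == pytest.approx(res[7.3], rel=1e-3, abs=1e-6)

    def test_broad_qst_recovery(self):
        """Clonal-replication fit recovers planted broad-sense Q_ST."""
        rng = np.random.default_rng(21)
        vals = []
        for rep in range(6):
            ng, r = 120, 3
            lab = rng.integers(0, 4, ng)
            s2p, s2g, s2e = 0.3, 0.6, 0.5   # truth: Qst = 0.3/1.5 = 0.2
            p = rng.normal(scale=np.sqrt(s2p), size=4)
            a = rng.normal(scale=np.sqrt(s2g), size=ng)
            gi = np.repeat(np.arange(ng), r)
            y = p[lab][gi] + a[gi] + rng.normal(scale=np.sqrt(s2e), size=ng * r)
            spec = clone_model_spec(y, lab[gi], gi)
            vals.append(broad_qst(spec, d=4).value)
        assert abs(np.median(vals) - 0.2) < 0.1

    def test_pst_algebra_and_degenerate_limits(self):
        rng = np.random.default_rng(3)
        ng, r = 60, 3
        lab = rng.integers(0, 3, ng)
        gi = np.repeat(np.arange(ng), r)
        K = np.eye(ng)
        y = (rng.normal(scale=1.0, size=3)[lab][gi]
             + rng.normal(size=ng)[gi] * 0.8 + rng.normal(size=ng * r) * 0.6)
        h2, pst, vc_h2, vc_pst = h2_pst(y, K, lab[gi], genotype_index=gi)
        sp, se = vc_pst["cluster"], vc_pst["residual"]
        if h2.value > 0 and sp > 0:
            expect = sp / (sp + 2 * h2.value * se)
            assert pst.value == pytest.approx(min(1.0, expect), rel=1e-9)
        assert 0 <= h2.value <= 1
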