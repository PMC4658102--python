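"""Binomial logistic fits for allele-frequency models.

Each diploid individual contributes two Bernoulli allele draws, so a locus
is modelled as Binomial(2, pi_i) with logit link.  The IRLS fitter below is
shared by the SPA-style cline scores and the SAM-style environment scan; it
reports the log-likelihood, slope covariance and a separation flag, and
caps the slope norm when the likelihood diverges under perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BinomialFit", "fit_allele_logistic", "logistic_tests"]

_SEPARATION_CAP = 25.0  # max slope norm on standardized predictors


@dataclass
class BinomialFit:
    coef: np.ndarray          # intercept first
    cov: np.ndarray | None    # inverse Fisher information (None if separated)
    loglik: float
    separated: bool
    converged: bool


def _binom_loglik(k, n, eta):
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def fit_allele_logistic(dosage: np.ndarray, Z: np.ndarray,
                        max_iter: int = 60, tol: float = 1e-10) -> BinomialFit:
    """IRLS fit of allele counts (0/1/2 of 2) on design ``Z`` (with intercept).

    Missing dosages are dropped.  If the slope norm exceeds the separation
    cap the coefficients are rescaled onto the cap, the fit flagged, and the
    covariance withheld (Wald inference is meaningless under separation).
    """
    ok = ~np.isnan(dosage)
    k = dosage[ok]
    Z = np.atleast_2d(Z)[ok]
    n = np.full(len(k), 2.0)
    beta = np.zeros(Z.shape[1])
    pbar = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(pbar / (1 - pbar))
    ll = _binom_loglik(k, n, Z @ beta)
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = Z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1 - p)
        # Fisher scoring step
        WZ = Z * w[:, None]
        H = Z.T @ WZ
        g = Z.T @ (k - n * p)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(Z.shape[1]), g)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        ll_new = _binom_loglik(k, n, Z @ beta_new)
        halv = 0
        while ll_new < ll - 1e-12 and halv < 20:
            beta_new = 0.5 * (beta_new + beta)
            ll_new = _binom_loglik(k, n, Z @ beta_new)
            halv += 1
        slope_norm = np.linalg.norm(beta_new[1:])
        if slope_norm > _SEPARATION_CAP:
            separated = True
            beta_new[1:] *= _SEPARATION_CAP / slope_norm
            ll_new = _binom_loglik(k, n, Z @ beta_new)
            beta = beta_new
            ll = ll_new
            break
        if abs(ll_new - ll) < tol * (1 + abs(ll)):
            beta, ll = beta_new, ll_new
            converged = True
            break
        beta, ll = beta_new, ll_new

    cov = None
    if not separated:
        eta = Z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1 - p)
        H = Z.T @ (Z * w[:, None])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
    return BinomialFit(coef=beta, cov=cov, loglik=ll,
                       separated=separated, converged=converged)


def logistic_tests(dosage: np.ndarray, z: np.ndarray) -> dict:
    """LR, Wald and score tests of a single-predictor allele model.

    All three compare logit(p) = a + b z against the intercept-only model;
    the statistics are asymptotically chi-square with 1 df.  Under
    separation the Wald p-value is withheld (NaN).
    """
    ok = ~np.isnan(dosage)
    k = dosage[ok]
    zz = np.asarray(z, dtype=float)[ok]
    n = np.full(len(k), 2.0)
    Z1 = np.column_stack([np.ones(len(k)), zz])

    full = fit_allele_logistic(dosage, np.column_stack([np.ones(len(dosage)), z]))
    pbar = np.clip(k.sum() / n.sum(), 1e-12, 1 - 1e-12)
    ll0 = _binom_loglik(k, n, np.full(len(k), np.log(pbar / (1 - pbar))))

    lr = max(0.0, 2.0 * (full.loglik - ll0))
    lr_p = float(stats.chi2.sf(lr, 1))

    if full.cov is not None and not full.separated:
        wald = float(full.coef[1] ** 2 / full.cov[1, 1])
        wald_p = float(stats.chi2.sf(wald, 1))
    else:
        wald, wald_p = np.nan, np.nan

    # score (Lagrange multiplier) test at the null fit
    p0 = pbar
    U = float(np.sum(zz * (k - n * p0)))
    w0 = n * p0 * (1 - p0)
    # information for (a, b) at the null, b-block conditioned on a
    i_aa = float(np.sum(w0))
    i_ab = float(np.sum(w0 * zz))
    i_bb = float(np.sum(w0 * zz**2))
    info = i_bb - i_ab**2 / i_aa
    score = U**2 / info if info > 0 else np.nan
    score_p = float(stats.chi2.sf(score, 1)) if np.isfinite(score) else np.nan

    return {
        "slope": float(full.coef[1]),
        "lr_stat": lr, "lr_p": lr_p,
        "wald_stat": wald, "wald_p": wald_p,
        "score_stat": float(score), "score_p": score_p,
        "separated": full.separated,
        "loglik_full": full.loglik, "loglik_null": ll0,
    }
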