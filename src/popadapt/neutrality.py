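"""Simulated Q_ST - F_ST neutrality test for quantitative traits.

A trait evolving neutrally in a subdivided population is expected to show
the same differentiation as neutral markers.  The null distribution of
Q_ST - F_ST for such a trait is built by parametric simulation following
the Whitlock-Guillaume logic: for each replicate a marker F is drawn (with
replacement) from the trimmed neutral per-locus F_ST vector; the neutral
among-group additive variance implied by F is obtained by inverting the
Q_ST definition with Q_ST set to F,

    s2_B = 2 s2_a F / (1 - F);

sampling noise is then injected with balanced normal theory: the
among-cluster mean square is (s2_B + v_m) chi2_{d-1} / (d-1), where v_m is
the sampling-variance floor of one cluster mean (from the fitted
components and the design), and the estimated among-group variance is
that mean square minus v_m, truncated at zero exactly as REML truncates;
the estimated within-group additive variance is s2_a * chi2_nu / nu with
nu the Satterthwaite effective degrees of freedom 2 (s2_a / se)^2 of the
REML estimate.  The simulated Q_ST re-assembles the ratio, and the test
compares the observed Q_ST minus the mean neutral F_ST to the simulated
Q_ST - F draws (one-sided toward divergent selection, +1-smoothed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixedmodel import QstEstimate, VarianceComponents

__all__ = ["NeutralNull", "simulate_neutral_null", "neutrality_pvalue",
           "cluster_mean_noise"]


def cluster_mean_noise(vc: VarianceComponents, n_per_cluster: float,
                       n_ramets: float = 1.0, G=None, clusters=None) -> float:
    """Sampling-variance floor of the among-cluster mean square.

    A cluster mean of genotype means carries sampling variance beyond the
    cluster effect — additive-value averaging plus ramet residuals — so
    the among-cluster mean square has a floor the neutral null must share.
    When the relationship matrix ``G`` and cluster ``labels`` are given
    the floor is computed exactly from the G blocks,

        A_kl = s2_a 1' G_kl 1 / (n_k n_l) + delta_kl s2_e / (r n_k),
        floor = [tr(A) - 1' A 1 / d] / (d - 1),

    which accounts for within-cluster relatedness; otherwise the
    independence approximation (s2_a + s2_e / r) / n is used.
    """
    s2a, s2e = vc["additive"], vc["residual"]
    if G is None or clusters is None:
        return float((s2a + s2e / n_ramets) / n_per_cluster)
    K = np.asarray(getattr(G, "G", G), dtype=float)
    labels = np.asarray(clusters)
    levels = np.unique(labels)
    d = len(levels)
    A = np.zeros((d, d))
    for i, li in enumerate(levels):
        mi = labels == li
        ni = mi.sum()
        for j, lj in enumerate(levels):
            mj = labels == lj
            A[i, j] = s2a * K[np.ix_(mi, mj)].sum() / (ni * mj.sum())
        A[i, i] += s2e / (n_ramets * ni)
    return float((np.trace(A) - A.sum() / d) / (d - 1))


@dataclass
class NeutralNull:
    draws: np.ndarray
    n_reps: int
    d: int
    sigma_a2_used: float
    nu_used: float
    source: str
    seed: int


def simulate_neutral_null(
    neutral_fst: np.ndarray,
    vc: VarianceComponents,
    d: int,
    n_reps: int = 100_000,
    seed: int = 0,
    noise_floor: float = 0.0,
    source: str = "trimmed neutral F_ST vector",
) -> NeutralNull:
    """Null draws of Q_ST,sim - F for a neutral trait (see module docstring).

    ``noise_floor`` is the per-cluster-mean sampling variance v_m (see
    :func:`cluster_mean_noise`); zero reduces to the pure chi-square
    scheme.
    """
    neutral_fst = np.asarray(neutral_fst, dtype=float)
    neutral_fst = neutral_fst[np.isfinite(neutral_fst)]
    if neutral_fst.size == 0:
        raise ValueError("empty neutral F_ST vector")
    if np.any((neutral_fst < 0) | (neutral_fst >= 1)):
        # slight negatives are a known property of the estimator; clamp
        neutral_fst = np.clip(neutral_fst, 0.0, 1.0 - 1e-9)
    sigma_a2 = vc["additive"]
    if sigma_a2 <= 0:
        raise ValueError("additive variance must be positive for the null")
    if d < 2:
        raise ValueError("need d >= 2 groups")

    se = np.nan
    if "additive" in vc.names:
        v = vc.cov_entry("additive", "additive")
        if np.isfinite(v) and v > 0:
            se = float(np.sqrt(v))
    nu = 2.0 * (sigma_a2 / se) ** 2 if np.isfinite(se) and se > 0 else np.inf

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    F = rng.choice(neutral_fst, size=n_reps, replace=True)
    s2_B = 2.0 * sigma_a2 * F / (1.0 - F)
    ms_between = (s2_B + noise_floor) * rng.chisquare(d - 1, size=n_reps) / (d - 1)
    est_between = np.maximum(ms_between - noise_floor, 0.0)
    if np.isinf(nu):
        est_within = np.full(n_reps, sigma_a2)
    else:
        est_within = sigma_a2 * rng.chisquare(nu, size=n_reps) / nu
    with np.errstate(invalid="ignore"):
        qst_sim = est_between / (est_between + 2.0 * est_within)
    qst_sim[~np.isfinite(qst_sim)] = 0.0  # F = 0 and nu = inf edge
    draws = qst_sim - F
    return NeutralNull(draws=draws, n_reps=n_reps, d=d,
                       sigma_a2_used=float(sigma_a2), nu_used=float(nu),
                       source=source, seed=seed)


def neutrality_pvalue(observed: QstEstimate, null: NeutralNull,
                      mean_neutral_fst: float, two_sided: bool = False) -> float:
    """Empirical p-value of the observed Q_ST against the neutral null.

    One-sided toward divergent selection by default: the trait is called
    adaptive when Q_ST exceeds the neutral expectation.  +1 smoothing keeps
    the p-value strictly positive.
    """
    if observed.d and observed.d != null.d:
        raise ValueError(f"group counts differ: observed d={observed.d}, "
                         f"null d={null.d}")
    delta = observed.value - mean_neutral_fst
    k_hi = int(np.sum(null.draws >= delta))
    p_hi = (1 + k_hi) / (null.n_reps + 1)
    if not two_sided:
        return float(p_hi)
    k_lo = int(np.sum(null.draws <= delta))
    p_lo = (1 + k_lo) / (null.n_reps + 1)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))
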