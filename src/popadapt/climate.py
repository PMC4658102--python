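"""Climate-envelope clustering and allele-frequency/environment association.

Individuals are grouped by their climate of origin (MAT, NFFD, MAP) with
PAM K-medoids on standardized variables, choosing K by the
Calinski-Harabasz criterion evaluated with the medoids as cluster centres.
The association scan regresses allele presence on each climate variable
with univariate logistic models, retains a model only when the likelihood
ratio, Wald and score tests all clear the Bonferroni family-wise threshold
alpha / (n_alleles x n_variables), and a companion routine regresses
arcsine-transformed cluster allele frequencies on cluster climate means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import logistic_tests
from .relatedness import GenotypeMatrix

logger = logging.getLogger("popadapt")

__all__ = [
    "ClusterAssignment",
    "kmedoids_ch",
    "sam_scan",
    "cluster_freq_regression",
]

CLIMATE_VARS = ["MAT", "NFFD", "MAP"]


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # 1..K
    medoid_indices: np.ndarray
    K: int
    ch_by_k: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PAM K-medoids with the Calinski-Harabasz criterion
# ---------------------------------------------------------------------------

def _pam(D: np.ndarray, k: int, max_swaps: int = 200) -> np.ndarray:
    """Classic PAM build + swap on a precomputed distance matrix.

    Deterministic: the greedy build and first-improvement swap break ties
    by index order.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(dmin - D[:, c], 0.0).sum() if c not in medoids else -1.0
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_swaps):
        improved = False
        for mi, m in enumerate(list(medoids)):
            for c in range(n):
                if c in medoids:
                    continue
                trial = sorted(medoids[:mi] + [c] + medoids[mi + 1:])
                tc = cost(trial)
                if tc < best - 1e-12:
                    medoids, best = trial, tc
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return np.asarray(medoids)


def _ch_score(Xs: np.ndarray, labels: np.ndarray, medoids: np.ndarray) -> float:
    """Calinski-Harabasz ratio with medoids as the cluster centres."""
    n, k = len(Xs), len(medoids)
    centre = Xs.mean(axis=0)
    W = 0.0
    B = 0.0
    for j, m in enumerate(medoids):
        members = Xs[labels == j]
        W += ((members - Xs[m]) ** 2).sum()
        B += len(members) * ((Xs[m] - centre) ** 2).sum()
    if W == 0:
        return np.inf
    return (B / (k - 1)) / (W / (n - k))


def kmedoids_ch(climate: pd.DataFrame, k_range=range(2, 9),
                seed: int = 0) -> ClusterAssignment:
    """PAM clustering of standardized climate variables, K chosen by CH.

    ``climate`` must hold the columns MAT, NFFD, MAP (any additional
    columns are ignored).  All k in ``k_range`` must satisfy
    2 <= k <= n/5.  Labels are 1..K; the seed only matters for degenerate
    ties (PAM itself is deterministic).
    """
    k_range = list(k_range)
    X = climate[CLIMATE_VARS].to_numpy(dtype=float)
    n = len(X)
    if not k_range or any(k < 2 or k > n / 5 for k in k_range):
        raise ValueError("each k must satisfy 2 <= k <= n/5")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant climate variable")
    Xs = (X - X.mean(axis=0)) / sd
    D = np.sqrt(((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=-1))

    ch_by_k = {}
    results = {}
    for k in k_range:
        medoids = _pam(D, k)
        labels = np.argmin(D[:, medoids], axis=1)
        ch_by_k[k] = _ch_score(Xs, labels, medoids)
        results[k] = (labels, medoids)
    K = max(ch_by_k, key=lambda k: (ch_by_k[k], -k))
    labels, medoids = results[K]
    return ClusterAssignment(labels=labels + 1, medoid_indices=medoids, K=K,
                             ch_by_k=ch_by_k)


# ---------------------------------------------------------------------------
# SAM-style logistic environment scan
# ---------------------------------------------------------------------------

def sam_scan(g: GenotypeMatrix, env: pd.DataFrame, alpha: float = 0.05,
             clusters=None, env_mode: str = "cluster-mean",
             variables=None) -> pd.DataFrame:
    """Univariate logistic scans of allele presence on climate variables.

    With ``env_mode='cluster-mean'`` (the subpopulation-average convention)
    every individual carries its cluster's mean for each variable
    (``clusters`` required); ``'individual'`` uses the values as given.
    A model passes only when the likelihood-ratio, Wald and score test
    p-values all fall below alpha / (n_alleles x n_variables).  Under
    separation the Wald p is withheld and the decision falls to the LR and
    score tests (logged).

    Returns one row per (allele, variable); ``attrs`` records the
    Bonferroni threshold and the number of models.
    """
    variables = list(variables) if variables is not None else [
        v for v in CLIMATE_VARS if v in env.columns
    ]
    if not variables:
        raise ValueError("no climate variables found")
    env_used = env[variables].copy().reset_index(drop=True)
    if env_mode == "cluster-mean":
        if clusters is None:
            raise ValueError("cluster labels required for cluster-mean mode")
        cl = pd.Series(np.asarray(clusters), name="_cl")
        env_used = env_used.groupby(cl).transform("mean")
    elif env_mode != "individual":
        raise ValueError(f"unknown env_mode {env_mode!r}")

    maf = g.maf()
    tested = np.flatnonzero(maf > 0)
    if len(tested) < g.n_loci:
        logger.info("sam_scan: skipped %d monomorphic loci",
                    g.n_loci - len(tested))
    n_models = len(tested) * len(variables)
    threshold = alpha / n_models

    rows = []
    for v in variables:
        z = env_used[v].to_numpy(dtype=float)
        if z.std() == 0:
            raise ValueError(f"environment variable {v} is constant")
        zs = (z - z.mean()) / z.std()
        for j in tested:
            r = logistic_tests(g.dosage[:, j], zs)
            ps = [r["lr_p"], r["score_p"]] + ([] if r["separated"] else [r["wald_p"]])
            ok = all(np.isfinite(p) and p < threshold for p in ps)
            if r["separated"]:
                logger.info("sam_scan: separation at %s x %s; Wald withheld",
                            g.loci["id"].iloc[j], v)
            rows.append((g.loci["id"].iloc[j], v, r["slope"],
                         r["lr_stat"], r["lr_p"], r["wald_stat"], r["wald_p"],
                         r["score_stat"], r["score_p"], r["separated"], ok))
    out = pd.DataFrame(rows, columns=[
        "id", "variable", "slope", "lr_stat", "lr_p", "wald_stat", "wald_p",
        "score_stat", "score_p", "separated", "pass"])
    out.attrs.update(threshold=threshold, n_models=n_models, alpha=alpha,
                     n_alleles=len(tested), n_variables=len(variables))
    return out


# ---------------------------------------------------------------------------
# Cluster-level frequency regressions (arcsine scale)
# ---------------------------------------------------------------------------

def cluster_freq_regression(g: GenotypeMatrix, clusters,
                            climate_cluster_means: pd.DataFrame) -> pd.DataFrame:
    """OLS of arcsine-root cluster allele frequencies on cluster climate.

    ``climate_cluster_means`` has one row per cluster (indexed by label)
    and one column per climate variable.  For each locus and variable the
    transformed frequencies t_k = arcsin(sqrt(f_k)) are regressed on the
    cluster means; boundary frequencies (0 or 1) transform to 0 or pi/2 and
    flag the locus.
    """
    clusters = np.asarray(clusters)
    levels = list(climate_cluster_means.index)
    if len(levels) < 3:
        raise ValueError("need >= 3 clusters for a regression")
    freqs = np.stack([
        np.nanmean(g.dosage[clusters == lev], axis=0) / 2.0 for lev in levels
    ])  # k x loci
    t = np.arcsin(np.sqrt(np.clip(freqs, 0.0, 1.0)))
    boundary = ((freqs == 0) | (freqs == 1)).any(axis=0)

    rows = []
    for v in climate_cluster_means.columns:
        x = climate_cluster_means[v].to_numpy(dtype=float)
        for j in range(g.n_loci):
            res = stats.linregress(x, t[:, j])
            rows.append((g.loci["id"].iloc[j], v, res.slope,
                         res.rvalue**2, res.pvalue, bool(boundary[j])))
    return pd.DataFrame(rows, columns=["id", "variable", "slope", "r2", "p",
                                       "boundary"])
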