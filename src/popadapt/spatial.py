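"""Spatial genetic structure: networks, Moran's I, sPCA, cline scores.

Coordinates are projected onto a planar km chart (azimuthal equidistant
about the sample centroid) so that distances at the sampling scale are
great-circle faithful without multi-zone projection seams.  Moran's I is

    I = n / sum_ij w_ij * sum_ij w_ij (x_i - xbar)(x_j - xbar)
        / sum_i (x_i - xbar)^2

with binary 0/1 neighbour weights for the distance-lag tests.  Spatial PCA
diagonalises (1/2n) X' (W + W') X for the node-centred dosage matrix X and
row-standardised weights W; each signed eigenvalue equals the product of
the axis score's variance and its Moran's I, separating global (positive,
isolation-by-distance-like) from local (negative) structure.  Significance
of either side comes from permutation of the rows of X over the nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .glm import fit_allele_logistic
from .relatedness import GenotypeMatrix

logger = logging.getLogger("popadapt")

__all__ = [
    "SpatialNetwork",
    "SpcaResult",
    "prepare_locations",
    "build_network",
    "morans_i",
    "morans_lag_profile",
    "spca",
    "spa_cline_scores",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclass
class SpatialNetwork:
    coords: np.ndarray          # n x 2, km
    adjacency: np.ndarray       # symmetric 0/1, zero diagonal
    weights: np.ndarray         # row-standardized
    construction: str

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("no self-edges allowed")
        iso = A.sum(axis=1) == 0
        if iso.any():
            logger.warning("network has %d isolated nodes", int(iso.sum()))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray     # signed, descending
    scores: np.ndarray          # n x n_axes
    axes: np.ndarray            # loci x n_axes loadings
    global_p: float
    local_p: float
    n_perm: int


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def prepare_locations(coords: pd.DataFrame, seed: int = 0):
    """Project lat/lon to a planar km chart and deduplicate locations.

    Input columns ``lat`` and ``lon`` (degrees); rows with missing
    coordinates are excluded (logged).  The projection is azimuthal
    equidistant about the sample centroid.  One individual is retained per
    unique (lat, lon) pair, chosen by a seeded RNG, so clonal collections
    at a shared site do not inflate spatial tests.

    Returns ``(projected, representatives)``: the projected table (columns
    ``x_km``, ``y_km`` plus originals) and the integer row positions of the
    deduplicated representative subset.
    """
    lat = coords["lat"].to_numpy(dtype=float)
    lon = coords["lon"].to_numpy(dtype=float)
    ok = np.isfinite(lat) & np.isfinite(lon)
    if (~ok).any():
        logger.info("prepare_locations: excluded %d rows with missing coordinates",
                    int((~ok).sum()))
    if np.any((lat[ok] < -90) | (lat[ok] > 90) | (lon[ok] < -180) | (lon[ok] > 180)):
        raise ValueError("coordinates out of range")
    df = coords.loc[ok].reset_index(drop=True)
    lat, lon = np.radians(lat[ok]), np.radians(lon[ok])
    lat0, lon0 = lat.mean(), lon.mean()

    # azimuthal equidistant about the centroid: range * bearing decomposition
    dlon = lon - lon0
    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    az = np.arctan2(
        np.sin(dlon) * np.cos(lat),
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon),
    )
    r = _EARTH_RADIUS_KM * c
    out = df.copy()
    out["x_km"] = r * np.sin(az)
    out["y_km"] = r * np.cos(az)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reps = []
    for _, idx in out.groupby([df["lat"], df["lon"]], sort=True).indices.items():
        reps.append(int(rng.choice(idx)))
    reps.sort()
    return out, np.asarray(reps)


# ---------------------------------------------------------------------------
# Connection networks
# ---------------------------------------------------------------------------

def build_network(coords, method: str = "knn", K: int = 10,
                  lo: float = 0.0, hi: float = 200.0) -> SpatialNetwork:
    """K-nearest-neighbour (union-symmetrised) or distance-band network.

    ``distance_band`` connects pairs with lo < d <= hi km.  KNN ties are
    resolved by node order.  Coincident nodes are rejected: deduplicate
    first with :func:`prepare_locations`.
    """
    if isinstance(coords, pd.DataFrame):
        xy = coords[["x_km", "y_km"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(coords, dtype=float)
    n = len(xy)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    off = d[~np.eye(n, dtype=bool)]
    if off.size and off.min() == 0:
        raise ValueError("coincident nodes; deduplicate locations first")

    if method == "knn":
        if n < K + 1:
            raise ValueError(f"need at least K+1={K + 1} nodes for knn")
        nn = NearestNeighbors(n_neighbors=K + 1).fit(xy)
        _, idx = nn.kneighbors(xy)
        A = np.zeros((n, n))
        for i in range(n):
            A[i, idx[i, 1:]] = 1.0
        A = np.maximum(A, A.T)  # union symmetrisation
        construction = f"knn(K={K})"
    elif method == "distance_band":
        A = ((d > lo) & (d <= hi)).astype(float)
        np.fill_diagonal(A, 0.0)
        construction = f"distance_band({lo}, {hi})"
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(rows[:, None] > 0, A / rows[:, None], 0.0)
    return SpatialNetwork(coords=xy, adjacency=A, weights=W,
                          construction=construction)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(x, net: SpatialNetwork, n_perm: int = 999, seed: int = 0,
             use_weights: str = "binary") -> dict:
    """Moran's I with a permutation p-value.

    ``use_weights='binary'`` uses the 0/1 adjacency (the distance-lag
    convention); ``'row'`` uses row-standardised weights.  The permutation
    test shuffles x over the nodes and is one-sided toward the observed
    deviation from the null expectation -1/(n-1).
    """
    x = np.asarray(x, dtype=float)
    W = net.adjacency if use_weights == "binary" else net.weights
    n = len(x)
    if x.std() == 0:
        raise ValueError("zero variance: Moran's I undefined for constant x")
    if W.sum() == 0:
        raise ValueError("network has no edges")

    def stat(v):
        vc = v - v.mean()
        return n / W.sum() * (vc @ W @ vc) / (vc @ vc)

    I = float(stat(x))
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = stat(rng.permutation(x))
    if I >= e_i:
        k = int(np.sum(perm >= I))
    else:
        k = int(np.sum(perm <= I))
    p = (1 + k) / (1 + n_perm)
    return {"I": I, "expected_I": e_i, "p_perm": float(p), "perm": perm}


def morans_lag_profile(x, coords, lag_width: float = 200.0,
                       n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Moran's I in successive distance bands of ``lag_width`` km.

    Bands run (0, w], (w, 2w], ... up to the maximum pairwise distance;
    bands without edges are skipped with a log entry.
    """
    if isinstance(coords, pd.DataFrame):
        xy = coords[["x_km", "y_km"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(coords, dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    dmax = d.max()
    rows = []
    lo = 0.0
    lag = 0
    while lo < dmax:
        hi = lo + lag_width
        net = build_network(xy, method="distance_band", lo=lo, hi=hi)
        if net.n_edges == 0:
            logger.info("lag (%g, %g] km has no pairs; skipped", lo, hi)
        else:
            res = morans_i(x, net, n_perm=n_perm, seed=seed + lag)
            rows.append((lo, hi, res["I"], res["expected_I"], res["p_perm"],
                         net.n_edges))
        lo = hi
        lag += 1
    return pd.DataFrame(
        rows, columns=["lag_lo_km", "lag_hi_km", "I", "expected_I", "p_perm",
                       "n_pairs"]
    )


# ---------------------------------------------------------------------------
# Spatial PCA
# ---------------------------------------------------------------------------

def _spca_eigs(Xc: np.ndarray, A: np.ndarray):
    """Signed spectrum and axes of (1/2n) X'(W+W')X via the row space of X."""
    n = Xc.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > 1e-10 * (s[0] if len(s) else 1.0)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    Us = U * s
    lam, Wv = _spectrum(Us, A)
    axes = Vt.T @ Wv                   # loci-space loadings, unit norm
    scores = Xc @ axes
    return lam, scores, axes, Us


def _spectrum(Us: np.ndarray, A: np.ndarray):
    """Eigen-spectrum of the quadratic form restricted to the row space.

    ``Us`` holds the left singular vectors of the centred dosage matrix
    scaled by their singular values; permuting its rows is equivalent to
    permuting genotype rows, which keeps permutation testing cheap.
    """
    n = Us.shape[0]
    M = Us.T @ (A @ Us) / n
    lam, Wv = np.linalg.eigh(0.5 * (M + M.T))
    order = np.argsort(lam)[::-1]
    return lam[order], Wv[:, order]


def spca(g: GenotypeMatrix | np.ndarray, net: SpatialNetwork,
         n_perm: int = 999, seed: int = 0) -> SpcaResult:
    """Spatial PCA of the node-level dosage matrix on ``net``.

    Rows of the dosage matrix must correspond one-to-one to network nodes.
    Missing dosages are mean-imputed before column centring.  The global
    (respectively local) test statistic is the sum of positive (absolute
    negative) eigenvalues, compared against its distribution under random
    reassignment of genotype rows to nodes.
    """
    if n_perm < 99:
        raise ValueError("n_perm < 99: permutation test undefined")
    X = g.dosage.copy() if isinstance(g, GenotypeMatrix) else np.array(g, dtype=float)
    if X.shape[0] != net.n_nodes:
        raise ValueError("genotype rows must match network nodes")
    col_mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.take(col_mean, np.nonzero(nan)[1])
    Xc = X - X.mean(axis=0)

    A = 0.5 * (net.weights + net.weights.T)
    lam, scores, axes, Us = _spca_eigs(Xc, A)
    g_obs = lam[lam > 0].sum()
    l_obs = -lam[lam < 0].sum()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g_cnt = l_cnt = 0
    n = Xc.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        lam_p, _ = _spectrum(Us[perm], A)
        if lam_p[lam_p > 0].sum() >= g_obs:
            g_cnt += 1
        if -lam_p[lam_p < 0].sum() >= l_obs:
            l_cnt += 1
    return SpcaResult(
        eigenvalues=lam, scores=scores, axes=axes,
        global_p=(1 + g_cnt) / (1 + n_perm),
        local_p=(1 + l_cnt) / (1 + n_perm),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# SPA-style logistic cline scores
# ---------------------------------------------------------------------------

def spa_cline_scores(g: GenotypeMatrix, predictors,
                     standardize: bool = True) -> pd.DataFrame:
    """Per-locus steepness of the allele-frequency cline over ``predictors``.

    For every polymorphic locus a logistic allele-frequency surface
    logit(p) = a + b'z is fitted over individuals (two allele draws per
    diploid); the score is the slope norm ||b||, which is invariant to
    allele relabelling.  Flags mark loci above the 95th and 99th
    percentiles of the score distribution; perfectly separated fits are
    capped and flagged.
    """
    Z = np.atleast_2d(np.asarray(predictors, dtype=float))
    if Z.shape[0] != g.n_individuals:
        Z = Z.T
    if standardize:
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    design = np.column_stack([np.ones(len(Z)), Z])

    scores = np.full(g.n_loci, np.nan)
    sep = np.zeros(g.n_loci, dtype=bool)
    maf = g.maf()
    for j in range(g.n_loci):
        if not (maf[j] > 0):
            continue
        fit = fit_allele_logistic(g.dosage[:, j], design)
        scores[j] = np.linalg.norm(fit.coef[1:])
        sep[j] = fit.separated
    valid = np.isfinite(scores)
    q95 = np.nanquantile(scores[valid], 0.95) if valid.any() else np.nan
    q99 = np.nanquantile(scores[valid], 0.99) if valid.any() else np.nan
    return pd.DataFrame({
        "id": g.loci["id"].to_numpy(),
        "score": scores,
        "separated": sep,
        "flag_5pct": valid & (scores >= q95),
        "flag_1pct": valid & (scores >= q99),
    })
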