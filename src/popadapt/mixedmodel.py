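"""REML variance components and the derived Q_ST / h-squared / P_ST ratios.

Three model forms are used downstream, all special cases of

    y = X beta + sum_i Z_i u_i + e,   u_i ~ N(0, s2_i K_i),  e ~ N(0, s2_e I)

* the animal model with a random climate-cluster effect and an individual
  additive effect whose covariance is the genomic relationship matrix
  (narrow-sense Q_ST = s2_p / (s2_p + 2 s2_a));
* the clonal-replication model where the additive term is replaced by a
  clone identity effect capturing total genetic variance (broad-sense
  Q_ST); and
* the heritability / P_ST pair: cluster as fixed with a GRM additive term
  (h2 = s2_a / (s2_a + s2_e)), and cluster as the only random term
  (P_ST = s2_p / (s2_p + 2 h2 s2_e)).

REML maximisation uses an expectation-maximisation warm-up followed by
average-information (AI) updates with step-halving; negative proposals are
truncated at zero and treated as boundary estimates.  Standard errors of
the ratios come from the delta method on the AI-based asymptotic
covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .relatedness import RelationshipMatrix

logger = logging.getLogger("popadapt")

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "QstEstimate",
    "reml_fit",
    "restricted_loglik",
    "narrow_qst",
    "broad_qst",
    "h2_pst",
    "animal_model_spec",
    "clone_model_spec",
    "cluster_design",
]


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class MixedModelSpec:
    """Response, fixed design and an ordered list of random terms.

    Each random term is ``(name, Z, K)`` with incidence matrix Z
    (n x q) and covariance K (q x q) or None for identity.  The residual
    is always an implicit identity term named ``"residual"``.

    Balanced-or-not clonal replication can be absorbed exactly: when the
    rows are genotype means, ``residual_scale`` carries the per-row
    residual variance multipliers 1/r_i and ``within`` the pair
    (df, SS) of the within-genotype contrasts, whose restricted likelihood
    -(df log(2 pi s2_e) + SS/s2_e)/2 is added analytically.  This keeps
    the replicated animal model at genotype-level cost.
    """

    y: np.ndarray
    X: np.ndarray
    random_terms: list
    residual_scale: np.ndarray | None = None
    within: tuple | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient")
        for name, Z, K in self.random_terms:
            Z = np.asarray(Z, dtype=float)
            if Z.shape[0] != n:
                raise ValueError(f"random term {name!r}: Z rows must match y")
            if K is not None and K.shape != (Z.shape[1], Z.shape[1]):
                raise ValueError(f"random term {name!r}: K must be q x q")
        if self.residual_scale is not None:
            self.residual_scale = np.asarray(self.residual_scale, dtype=float).ravel()
            if self.residual_scale.shape[0] != n or np.any(self.residual_scale <= 0):
                raise ValueError("residual_scale must be n positive multipliers")
        if self.within is not None:
            df, ss = self.within
            if df < 0 or ss < 0:
                raise ValueError("within must be non-negative (df, SS)")

    @property
    def names(self) -> list[str]:
        return [t[0] for t in self.random_terms] + ["residual"]

    def covariance_parts(self) -> list[np.ndarray]:
        """The n x n matrices V_i = Z_i K_i Z_i' plus the residual identity."""
        n = len(self.y)
        parts = []
        for _, Z, K in self.random_terms:
            Z = np.asarray(Z, dtype=float)
            parts.append(Z @ Z.T if K is None else Z @ K @ Z.T)
        if self.residual_scale is None:
            parts.append(np.eye(n))
        else:
            parts.append(np.diag(self.residual_scale))
        return parts


@dataclass
class VarianceComponents:
    estimates: dict
    cov: np.ndarray
    converged: bool
    n_iter: int
    loglik_restricted: float
    identifiable: bool = True
    boundary: list = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]

    @property
    def names(self) -> list[str]:
        return list(self.estimates)

    def cov_entry(self, a: str, b: str) -> float:
        names = self.names
        return float(self.cov[names.index(a), names.index(b)])


@dataclass
class QstEstimate:
    value: float
    se: float
    kind: str  # narrow | broad | pst | h2
    d: int = 0
    degenerate: bool = False


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def restricted_loglik(spec: MixedModelSpec, sigma2, parts=None) -> float:
    """Restricted log-likelihood (constants included) at variances ``sigma2``.

    The last element of ``sigma2`` is the residual variance.  Used both by
    the fitter and, in tests, as the objective for independent direct
    maximisation.
    """
    parts = spec.covariance_parts() if parts is None else parts
    sigma2 = np.asarray(sigma2, dtype=float)
    n = len(spec.y)
    V = sum(s * P for s, P in zip(sigma2, parts))
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv_y = linalg.cho_solve(cf, spec.y)
    Vinv_X = linalg.cho_solve(cf, spec.X)
    XtVinvX = spec.X.T @ Vinv_X
    sign, logdetXVX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVinvX, spec.X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    p = spec.X.shape[1]
    ll = float(
        -0.5 * (logdetV + logdetXVX + spec.y @ Py + (n - p) * np.log(2 * np.pi))
    )
    if spec.within is not None:
        df, ss = spec.within
        s2e = sigma2[-1]
        if df > 0:
            if s2e <= 0:
                return -np.inf
            ll += -0.5 * (df * np.log(2 * np.pi * s2e) + ss / s2e)
    return ll


def _pmat_quantities(spec, sigma2, parts):
    """P y, tr(P V_i), y' P V_i P y and the AI matrix at ``sigma2``."""
    V = sum(s * P for s, P in zip(sigma2, parts))
    cf = linalg.cho_factor(V, lower=True)
    n = len(spec.y)
    Vinv = linalg.cho_solve(cf, np.eye(n))
    Vinv_X = Vinv @ spec.X
    XtVinvX = spec.X.T @ Vinv_X
    Pmat = Vinv - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T)
    Py = Pmat @ spec.y
    k = len(parts)
    trPV = np.array([np.sum(Pmat * P.T) for P in parts])
    ViPy = [P @ Py for P in parts]
    yPViPy = np.array([Py @ v for v in ViPy])
    PViPy = [Pmat @ v for v in ViPy]
    AI = 0.5 * np.array([[ViPy[i] @ PViPy[j] for j in range(k)] for i in range(k)])
    if spec.within is not None:
        df, ss = spec.within
        s2e = sigma2[-1]
        if df > 0:
            trPV[k - 1] += df / s2e
            yPViPy[k - 1] += ss / s2e**2
            AI[k - 1, k - 1] += 0.5 * ss / s2e**3
    grad = -0.5 * (trPV - yPViPy)
    return Py, trPV, yPViPy, AI, grad


def _check_identifiable(parts) -> bool:
    """False when two covariance parts are numerically proportional."""
    normed = []
    for P in parts:
        f = np.linalg.norm(P)
        normed.append(P / f if f > 0 else P)
    for i in range(len(normed)):
        for j in range(i + 1, len(normed)):
            if np.linalg.norm(normed[i] - normed[j]) < 1e-10 * normed[i].shape[0]:
                return False
    return True


def reml_fit(
    spec: MixedModelSpec,
    tol: float = 1e-8,
    grad_tol: float = 1e-6,
    max_iter: int = 200,
    n_em: int = 6,
) -> VarianceComponents:
    """REML estimates by EM warm-up then average-information updates.

    Convergence requires both a relative restricted-log-likelihood change
    below ``tol`` and a scaled gradient norm below ``grad_tol`` (gradient
    components of boundary-pinned parameters excluded).  Components whose
    updates push below zero are pinned at the boundary.  The asymptotic
    covariance is the inverse AI matrix over interior components.
    """
    parts = spec.covariance_parts()
    names = spec.names
    k = len(parts)
    n = len(spec.y)
    p = spec.X.shape[1]
    if n <= p + 0:
        raise ValueError("not enough observations for the fixed effects")
    if spec.within is not None and spec.within[0] > 0:
        # the residual is identified analytically by the within-genotype
        # contrasts; only the remaining structures can be confounded
        identifiable = _check_identifiable(parts[:-1]) if k > 2 else True
    else:
        identifiable = _check_identifiable(parts)
    if not identifiable:
        logger.warning("reml_fit: covariance structures are confounded; "
                       "components are not separately identifiable")

    vary = float(np.var(spec.y, ddof=1))
    if vary == 0:
        raise ValueError("response has zero variance")
    floor = 1e-10 * vary
    sigma2 = np.full(k, vary / k)
    pinned = np.zeros(k, dtype=bool)

    ll = restricted_loglik(spec, sigma2, parts)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Py, trPV, yPViPy, AI, grad = _pmat_quantities(spec, sigma2, parts)
        active = ~pinned
        # boundary components stay pinned unless the gradient pulls inward
        release = pinned & (grad > grad_tol)
        if release.any():
            pinned &= ~release
            sigma2[release] = floor * 10
            active = ~pinned

        gnorm = np.linalg.norm(grad[active]) / max(1.0, abs(ll))
        if it > 1 and abs(ll - ll_prev) <= tol * (1 + abs(ll)) and gnorm <= grad_tol:
            converged = True
            break
        ll_prev = ll

        if it <= n_em:
            # EM-flavoured fixed-point update: multiplicative, positivity kept
            new = sigma2.copy()
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = yPViPy / trPV
            ratio[~np.isfinite(ratio)] = 1.0
            new[active] = sigma2[active] * np.clip(ratio[active], 0.1, 10.0)
        else:
            def ai_step(idx):
                try:
                    return np.linalg.solve(AI[np.ix_(idx, idx)], grad[idx])
                except np.linalg.LinAlgError:
                    return grad[idx] / np.maximum(np.diag(AI)[idx], 1e-12)

            ia = np.flatnonzero(active)
            new = sigma2.copy()
            new[ia] = sigma2[ia] + ai_step(ia)
            hit = new < floor
            if hit.any():
                # pin boundary-bound components and re-solve for the rest
                new[hit] = floor
                rest = np.flatnonzero(active & ~hit)
                if len(rest):
                    new[rest] = sigma2[rest] + ai_step(rest)

        # truncate negatives to the boundary
        hit = new < floor
        new[hit] = floor
        ll_new = restricted_loglik(spec, new, parts)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            new = 0.5 * (new + sigma2)
            new[new < floor] = floor
            ll_new = restricted_loglik(spec, new, parts)
            halvings += 1
        if ll_new < ll - 1e-6 and it > n_em:
            # AI step failed badly even after halving; fall back to EM step
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = yPViPy / trPV
            ratio[~np.isfinite(ratio)] = 1.0
            new = sigma2.copy()
            new[active] = sigma2[active] * np.clip(ratio[active], 0.1, 10.0)
            new[new < floor] = floor
            ll_new = restricted_loglik(spec, new, parts)
        pinned |= new <= floor * 1.0000001
        pinned &= np.arange(k) != (k - 1)  # residual variance never pinned
        sigma2 = new
        ll = ll_new

    if not converged:
        logger.warning("reml_fit: no convergence after %d iterations", it)

    # asymptotic covariance over interior components from the AI matrix
    _, _, _, AI, _ = _pmat_quantities(spec, sigma2, parts)
    cov = np.full((k, k), np.nan)
    interior = np.flatnonzero(~pinned)
    if len(interior):
        try:
            cov_int = np.linalg.inv(AI[np.ix_(interior, interior)])
            for a, ia in enumerate(interior):
                for b, ib in enumerate(interior):
                    cov[ia, ib] = cov_int[a, b]
        except np.linalg.LinAlgError:
            pass

    est = {nm: (0.0 if pinned[i] else float(sigma2[i]))
           for i, nm in enumerate(names)}
    # report exact zeros for boundary components
    for i in range(k):
        if sigma2[i] <= floor * 1.0000001 and i != k - 1:
            est[names[i]] = 0.0
    return VarianceComponents(
        estimates=est,
        cov=cov,
        converged=converged,
        n_iter=it,
        loglik_restricted=float(restricted_loglik(spec, sigma2, parts)),
        identifiable=identifiable,
        boundary=[names[i] for i in range(k) if pinned[i]],
    )


# ---------------------------------------------------------------------------
# Design helpers
# ---------------------------------------------------------------------------

def cluster_design(labels) -> np.ndarray:
    """0/1 incidence matrix mapping observations to cluster levels."""
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    Z = np.zeros((len(labels), len(levels)))
    for j, lev in enumerate(levels):
        Z[labels == lev, j] = 1.0
    return Z


def _expand_grm(G: np.ndarray | RelationshipMatrix, genotype_index) -> tuple:
    """Incidence Z mapping records to genotypes plus the GRM as K."""
    K = G.G if isinstance(G, RelationshipMatrix) else np.asarray(G, dtype=float)
    gi = np.asarray(genotype_index)
    Z = np.zeros((len(gi), K.shape[0]))
    Z[np.arange(len(gi)), gi] = 1.0
    return Z, K


def collapse_ramets(y, clusters, genotype_index):
    """Genotype means plus the within-genotype contrast summary.

    Returns ``(ybar, clusters_g, genotype_rows, residual_scale, within)``
    where ``residual_scale`` holds 1/r_i and ``within`` the (df, SS) pair
    of the replicate contrasts.  Every record of a genotype must share its
    cluster label (ramets are planted copies of one collection).
    """
    y = np.asarray(y, dtype=float).ravel()
    gi = np.asarray(genotype_index)
    clusters = np.asarray(clusters)
    levels, inv, r = np.unique(gi, return_inverse=True, return_counts=True)
    ybar = np.bincount(inv, weights=y) / r
    cl_g = np.empty(len(levels), dtype=clusters.dtype)
    for j, lev in enumerate(levels):
        labs = np.unique(clusters[gi == lev])
        if len(labs) > 1:
            raise ValueError(f"genotype {lev} spans multiple clusters")
        cl_g[j] = labs[0]
    ss = float(np.sum((y - ybar[inv]) ** 2))
    df = int(len(y) - len(levels))
    return ybar, cl_g, levels, 1.0 / r, (df, ss)


def animal_model_spec(y, clusters, G, genotype_index=None) -> MixedModelSpec:
    """Intercept-only fixed part, random cluster term, GRM additive term.

    ``genotype_index`` maps each record to its genotype's row in G (defaults
    to the identity when records and genotypes are one-to-one).  Clonal
    replicates are collapsed to genotype means with the within-clone
    contrasts absorbed analytically, which is likelihood-exact.
    """
    y = np.asarray(y, dtype=float).ravel()
    if genotype_index is None:
        genotype_index = np.arange(len(y))
    gi = np.asarray(genotype_index)
    K_full = G.G if isinstance(G, RelationshipMatrix) else np.asarray(G, dtype=float)
    if len(np.unique(gi)) < len(gi):
        ybar, cl_g, rows, rscale, within = collapse_ramets(y, clusters, gi)
        Zp = cluster_design(cl_g)
        K = K_full[np.ix_(rows, rows)]
        return MixedModelSpec(
            y=ybar, X=np.ones((len(ybar), 1)),
            random_terms=[("cluster", Zp, None), ("additive", np.eye(len(rows)), K)],
            residual_scale=rscale, within=within,
        )
    X = np.ones((len(y), 1))
    Zp = cluster_design(clusters)
    Za, K = _expand_grm(G, gi)
    return MixedModelSpec(y=y, X=X, random_terms=[
        ("cluster", Zp, None), ("additive", Za, K),
    ])


def clone_model_spec(y, clusters, genotype_index) -> MixedModelSpec:
    """Cluster random term plus clone-identity genetic term (broad sense).

    Requires clonal replication: with a single ramet per genotype the clone
    and residual structures coincide and the model is rejected.  Built in
    the collapsed (genotype-mean) representation.
    """
    y = np.asarray(y, dtype=float).ravel()
    gi = np.asarray(genotype_index)
    if len(np.unique(gi)) == len(gi):
        raise ValueError(
            "clone and residual effects are confounded without ramet replication"
        )
    ybar, cl_g, rows, rscale, within = collapse_ramets(y, clusters, gi)
    Zp = cluster_design(cl_g)
    return MixedModelSpec(
        y=ybar, X=np.ones((len(ybar), 1)),
        random_terms=[("cluster", Zp, None), ("clone", np.eye(len(rows)), None)],
        residual_scale=rscale, within=within,
    )


# ---------------------------------------------------------------------------
# Ratio statistics
# ---------------------------------------------------------------------------

def _ratio_delta_se(vc: VarianceComponents, num: str, den_extra: str,
                    factor: float) -> float:
    """Delta-method SE of s2_num / (s2_num + factor * s2_den_extra)."""
    sp = vc[num]
    sa = vc[den_extra]
    den = sp + factor * sa
    if den <= 0:
        return np.nan
    dnum = factor * sa / den**2
    dden = -factor * sp / den**2
    g = np.array([dnum, dden])
    names = vc.names
    idx = [names.index(num), names.index(den_extra)]
    C = vc.cov[np.ix_(idx, idx)]
    if not np.all(np.isfinite(C)):
        return np.nan
    var = float(g @ C @ g)
    return float(np.sqrt(var)) if var >= 0 else np.nan


def narrow_qst(vc: VarianceComponents, d: int) -> QstEstimate:
    """Narrow-sense Q_ST = s2_cluster / (s2_cluster + 2 s2_additive)."""
    sp, sa = vc["cluster"], vc["additive"]
    if sp == 0.0 and sa == 0.0:
        return QstEstimate(value=np.nan, se=np.nan, kind="narrow", d=d,
                           degenerate=True)
    value = sp / (sp + 2.0 * sa)
    se = _ratio_delta_se(vc, "cluster", "additive", 2.0)
    return QstEstimate(value=float(np.clip(value, 0.0, 1.0)), se=se,
                       kind="narrow", d=d)


def broad_qst(spec: MixedModelSpec, d: int, **fit_kwargs) -> QstEstimate:
    """Broad-sense Q_ST from a clonal-replication fit (no marker matrix).

    ``spec`` must contain a ``cluster`` and a ``clone`` random term (see
    :func:`clone_model_spec`); the clone variance is the total genetic
    variance, so Q_ST = s2_cluster / (s2_cluster + 2 s2_clone).
    """
    names = [t[0] for t in spec.random_terms]
    if "cluster" not in names or "clone" not in names:
        raise ValueError("broad_qst needs cluster and clone random terms")
    vc = reml_fit(spec, **fit_kwargs)
    sp, sg = vc["cluster"], vc["clone"]
    if sp == 0.0 and sg == 0.0:
        return QstEstimate(value=np.nan, se=np.nan, kind="broad", d=d,
                           degenerate=True)
    if sg == 0.0:
        return QstEstimate(value=1.0, se=np.nan, kind="broad", d=d,
                           degenerate=True)
    value = sp / (sp + 2.0 * sg)
    se = _ratio_delta_se(vc, "cluster", "clone", 2.0)
    return QstEstimate(value=float(np.clip(value, 0.0, 1.0)), se=se,
                       kind="broad", d=d)


def h2_pst(y, G, clusters, genotype_index=None, **fit_kwargs):
    """Heritability and P_ST from their two separate fits.

    h2 comes from the model with cluster as a *fixed* effect and a GRM
    additive term: h2 = s2_a / (s2_a + s2_e).  The cluster and residual
    variances for P_ST come from the model with cluster as the only random
    term; P_ST = s2_p / (s2_p + 2 h2 s2_e) combines the two fits exactly as
    the estimator is defined, even though their residual variances refer to
    different models.

    Returns ``(h2: QstEstimate, pst: QstEstimate, vc_h2, vc_pst)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if genotype_index is None:
        genotype_index = np.arange(len(y))
    gi = np.asarray(genotype_index)
    clusters = np.asarray(clusters)
    d = len(pd.unique(clusters))

    K_full = G.G if isinstance(G, RelationshipMatrix) else np.asarray(G, dtype=float)
    replicated = len(np.unique(gi)) < len(gi)
    if replicated:
        ybar, cl_g, rows, rscale, within = collapse_ramets(y, clusters, gi)
        Zc_g = cluster_design(cl_g)
        X_h2 = np.column_stack([np.ones(len(ybar)), Zc_g[:, 1:]])
        spec_h2 = MixedModelSpec(
            y=ybar, X=X_h2,
            random_terms=[("additive", np.eye(len(rows)),
                           K_full[np.ix_(rows, rows)])],
            residual_scale=rscale, within=within,
        )
    else:
        # fixed part: intercept + cluster contrasts (drop first level)
        Zc = cluster_design(clusters)
        X_h2 = np.column_stack([np.ones(len(y)), Zc[:, 1:]])
        Za, K = _expand_grm(G, gi)
        spec_h2 = MixedModelSpec(y=y, X=X_h2, random_terms=[("additive", Za, K)])
    vc_h2 = reml_fit(spec_h2, **fit_kwargs)
    sa, se_ = vc_h2["additive"], vc_h2["residual"]
    if sa + se_ <= 0:
        h2 = QstEstimate(np.nan, np.nan, "h2", d, degenerate=True)
    else:
        h2val = sa / (sa + se_)
        h2se = _ratio_delta_se(vc_h2, "additive", "residual", 1.0)
        h2 = QstEstimate(float(np.clip(h2val, 0, 1)), h2se, "h2", d,
                         degenerate=not vc_h2.converged)

    if replicated:
        spec_pst = MixedModelSpec(
            y=ybar, X=np.ones((len(ybar), 1)),
            random_terms=[("cluster", Zc_g, None)],
            residual_scale=rscale, within=within,
        )
    else:
        spec_pst = MixedModelSpec(
            y=y, X=np.ones((len(y), 1)),
            random_terms=[("cluster", Zc, None)],
        )
    vc_pst = reml_fit(spec_pst, **fit_kwargs)
    sp, sep = vc_pst["cluster"], vc_pst["residual"]
    if h2.value == 0 or np.isnan(h2.value):
        degen = sp > 0
        pst = QstEstimate(value=1.0 if degen else np.nan, se=np.nan,
                          kind="pst", d=d, degenerate=True)
    else:
        denom = sp + 2.0 * h2.value * sep
        pst_val = sp / denom if denom > 0 else np.nan
        # delta method treating the two fits as independent
        dsp = 2.0 * h2.value * sep / denom**2
        dsep = -2.0 * h2.value * sp / denom**2
        dh2 = -2.0 * sep * sp / denom**2
        names = vc_pst.names
        C = vc_pst.cov[np.ix_([names.index("cluster"), names.index("residual")],
                              [names.index("cluster"), names.index("residual")])]
        var = np.nan
        if np.all(np.isfinite(C)) and np.isfinite(h2.se):
            var = (np.array([dsp, dsep]) @ C @ np.array([dsp, dsep])
                   + (dh2 * h2.se) ** 2)
        pst = QstEstimate(
            value=float(np.clip(pst_val, 0, 1)),
            se=float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else np.nan,
            kind="pst", d=d,
            degenerate=not (vc_h2.converged and vc_pst.converged),
        )
    return h2, pst, vc_h2, vc_pst
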