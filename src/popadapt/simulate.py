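"""Synthetic genotype / climate / phenotype generators with known truth.

The generators emulate the study design every downstream stage assumes: a
range-wide tree collection falling into ~4 climate-defined subpopulations
with very low marker differentiation (mean F_ST around 0.01), continuous
isolation-by-distance, clonally replicated common-garden phenotypes with an
additive architecture, a handful of clinal "selected" loci, and correlated
temperature/precipitation surfaces.

Every generator draws from its own RNG stream derived from
``SimConfig.seed`` via ``numpy`` spawn keys (one fixed key per generator),
so modules can be exercised independently yet reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .relatedness import GenotypeMatrix, RelationshipMatrix

logger = logging.getLogger("popadapt")

__all__ = [
    "SimConfig",
    "SimTruth",
    "sim_island_genotypes",
    "sim_ibd_genotypes",
    "sim_clinal_loci",
    "sim_climate",
    "sim_phenotypes",
    "simulate_dataset",
]

#: fixed spawn keys: one independent RNG stream per generator
_STREAMS = {"island": 0, "ibd": 1, "clinal": 2, "climate": 3, "phenotype": 4,
            "coords": 5}

#: climate-zone parameter table for the default four zones: MAT (degC),
#: NFFD (days), MAP (mm) — a coastal-to-interior Pacific-Northwest-like
#: gradient with temperature and frost-free days rising together.
_ZONE_MAT = np.array([4.2, 6.4, 8.1, 9.5])
_ZONE_NFFD = np.array([175.4, 215.2, 267.2, 287.1])
_ZONE_MAP = np.array([744.2, 1517.0, 1571.8, 2805.9])


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic study.

    Defaults encode the assumed study conditions: four climate demes of ~100
    genotypes, 5000 array-like SNPs, mean F_ST of about 0.01, a 1000 km
    landscape with 50 km dispersal scale, three clonal ramets per genotype,
    heritability 0.5 and trait divergence Q_ST 0.2.
    """

    n_pops: int = 4
    n_per_pop: int = 100
    n_loci: int = 5000
    target_fst: float = 0.01
    n_clinal_loci: int = 50
    cline_slope: float = 0.01  # logit units per km (or per predictor unit)
    h2_true: float = 0.5
    qst_true: float = 0.2
    n_ramets: int = 3
    landscape_extent: tuple = (1000.0, 1000.0)
    dispersal_sigma: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_per_pop", "n_loci", "n_ramets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.target_fst < 1):
            raise ValueError("target_fst must be in [0, 1)")
        if not (0 <= self.qst_true < 1):
            raise ValueError("qst_true must be in [0, 1)")
        if not (0 <= self.h2_true <= 1):
            raise ValueError("h2_true must be in [0, 1]")
        if self.n_clinal_loci < 0 or self.n_clinal_loci > self.n_loci:
            raise ValueError("n_clinal_loci must be in [0, n_loci]")
        if min(self.landscape_extent) <= 0 or self.dispersal_sigma <= 0:
            raise ValueError("landscape_extent and dispersal_sigma must be positive")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators."""

    cluster_labels: np.ndarray | None = None
    clinal_locus_ids: list = field(default_factory=list)
    variance_components: dict = field(default_factory=dict)
    deme_freqs: np.ndarray | None = None
    climate_zone_labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


def _locus_meta(n_loci: int, n_chromosomes: int = 19) -> pd.DataFrame:
    chrom = (np.arange(n_loci) % n_chromosomes) + 1
    pos = (np.arange(n_loci) // n_chromosomes + 1) * 1000
    return pd.DataFrame(
        {"id": [f"snp{j}" for j in range(n_loci)], "chrom": chrom, "pos": pos}
    )


# ---------------------------------------------------------------------------
# Island-model genotypes (Balding-Nichols)
# ---------------------------------------------------------------------------

def sim_island_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Neutral island-model genotypes at a target mean F_ST.

    Ancestral frequencies are uniform on (0.05, 0.95); deme frequencies are
    Balding-Nichols Beta draws at strength ``target_fst`` (a single
    panmictic pool when the target is zero); dosages are Binomial(2, p_deme)
    with no missingness.
    """
    rng = _rng(cfg.seed, "island")
    p0 = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    if cfg.target_fst == 0:
        deme_p = np.repeat(p0[None, :], cfg.n_pops, axis=0)
    else:
        F = cfg.target_fst
        shape = (1.0 - F) / F
        deme_p = rng.beta(p0[None, :] * shape, (1.0 - p0[None, :]) * shape,
                          size=(cfg.n_pops, cfg.n_loci))
    labels = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)
    dosage = rng.binomial(2, deme_p[labels, :]).astype(float)
    samples = [f"ind{i}" for i in range(len(labels))]
    g = GenotypeMatrix(dosage=dosage, loci=_locus_meta(cfg.n_loci), samples=samples)
    truth = SimTruth(cluster_labels=labels, deme_freqs=deme_p)
    return g, truth


# ---------------------------------------------------------------------------
# Isolation-by-distance genotypes (spatially correlated frequencies)
# ---------------------------------------------------------------------------

def sim_ibd_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes under continuous isolation by distance.

    Individuals are scattered uniformly on the landscape; per locus the
    logit allele frequency is an ancestral value plus a Gaussian random
    field with squared-exponential correlation of range ``dispersal_sigma``
    km, so allele-frequency similarity decays smoothly with distance.  As
    the dispersal scale grows without bound the field becomes spatially
    constant and the panel is effectively panmictic.
    """
    rng = _rng(cfg.seed, "ibd")
    n = cfg.n_pops * cfg.n_per_pop
    ex, ey = cfg.landscape_extent
    coords = np.column_stack([rng.uniform(0, ex, n), rng.uniform(0, ey, n)])
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    sigma_field2 = 0.5  # logit-scale field variance: weak, IBD-like structure
    C = sigma_field2 * np.exp(-d2 / (2.0 * cfg.dispersal_sigma**2))
    C[np.diag_indices(n)] += 1e-8
    L = np.linalg.cholesky(C)
    p0 = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    fields = L @ rng.standard_normal((n, cfg.n_loci))
    logit = np.log(p0 / (1 - p0))[None, :] + fields
    p = 1.0 / (1.0 + np.exp(-logit))
    dosage = rng.binomial(2, p).astype(float)
    samples = [f"ind{i}" for i in range(n)]
    g = GenotypeMatrix(dosage=dosage, loci=_locus_meta(cfg.n_loci), samples=samples)
    coords_df = pd.DataFrame(coords, columns=["x_km", "y_km"])
    coords_df.insert(0, "id", samples)
    return g, coords_df


# ---------------------------------------------------------------------------
# Clinal "selected" loci
# ---------------------------------------------------------------------------

def sim_clinal_loci(base: GenotypeMatrix, predictor, cfg: SimConfig,
                    truth: SimTruth | None = None) -> GenotypeMatrix:
    """Overwrite ``n_clinal_loci`` random loci with logistic clines.

    ``predictor`` is one value per individual: a km-scaled landscape axis
    (then ``cline_slope`` is logit units per km) or a climate variable (a
    DataFrame's ``MAT`` column is used; the slope is then per degree).  The
    overwritten frequency is logistic(logit(p0) + slope * centered
    predictor); remaining loci are untouched.  A zero slope leaves the
    overwritten loci indistinguishable from neutral ones (warned).
    """
    if isinstance(predictor, pd.DataFrame):
        predictor = predictor["MAT"].to_numpy(dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(x) != base.n_individuals:
        raise ValueError("predictor must align with individuals")
    if cfg.n_clinal_loci == 0:
        return base
    if cfg.cline_slope == 0:
        logger.warning("sim_clinal_loci: slope 0 plants no detectable cline")

    rng = _rng(cfg.seed, "clinal")
    idx = rng.choice(base.n_loci, size=cfg.n_clinal_loci, replace=False)
    idx.sort()
    xc = x - x.mean()
    dosage = base.dosage.copy()
    for j in idx:
        p0 = rng.uniform(0.2, 0.8)
        p = 1.0 / (1.0 + np.exp(-(np.log(p0 / (1 - p0)) + cfg.cline_slope * xc)))
        dosage[:, j] = rng.binomial(2, p)
    out = GenotypeMatrix(dosage=dosage, loci=base.loci.copy(), samples=list(base.samples))
    ids = base.loci["id"].iloc[idx].tolist()
    if truth is not None:
        truth.clinal_locus_ids = ids
    return out


# ---------------------------------------------------------------------------
# Climate surfaces
# ---------------------------------------------------------------------------

def sim_climate(coords, seed: int, n_zones: int = 4,
                noise_scale: float = 1.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Zone-structured MAT / NFFD / MAP values for each individual.

    Zones are spatially coherent (k-means on the coordinates); each zone
    carries fixed MAT/NFFD/MAP means on a coastal-to-interior gradient, and
    individuals add correlated within-zone noise (MAT and NFFD noise share
    correlation 0.7, matching their positive ecological coupling).  MAP is
    clipped at zero.  Returns the climate table and the true zone labels.
    """
    from sklearn.cluster import KMeans

    if isinstance(coords, pd.DataFrame):
        xy = coords[["x_km", "y_km"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(coords, dtype=float)
    rng = _rng(seed, "climate")
    km = KMeans(n_clusters=n_zones, n_init=10, random_state=seed % (2**31))
    # order zones along the dominant landscape axis so the climate gradient
    # is geographically monotone
    labels_raw = km.fit_predict(xy)
    order = np.argsort(km.cluster_centers_[:, 0])
    relabel = np.empty(n_zones, dtype=int)
    relabel[order] = np.arange(n_zones)
    labels = relabel[labels_raw]

    t = np.linspace(0, 1, n_zones)
    mat_means = np.interp(t, np.linspace(0, 1, 4), _ZONE_MAT)
    nffd_means = np.interp(t, np.linspace(0, 1, 4), _ZONE_NFFD)
    map_means = np.interp(t, np.linspace(0, 1, 4), _ZONE_MAP)

    n = len(xy)
    z1 = rng.standard_normal(n)
    z2 = 0.7 * z1 + np.sqrt(1 - 0.7**2) * rng.standard_normal(n)
    mat = mat_means[labels] + noise_scale * 0.5 * z1
    nffd = nffd_means[labels] + noise_scale * 8.0 * z2
    mapp = np.clip(map_means[labels] + noise_scale * 100.0 * rng.standard_normal(n),
                   0.0, None)
    nffd = np.clip(nffd, 0.0, 366.0)
    climate = pd.DataFrame({"MAT": mat, "NFFD": nffd, "MAP": mapp})
    return climate, labels


# ---------------------------------------------------------------------------
# Phenotypes with additive architecture and clonal ramets
# ---------------------------------------------------------------------------

def sim_phenotypes(G, clusters, cfg: SimConfig,
                   exact_cluster_variance: bool = True
                   ) -> tuple[pd.DataFrame, SimTruth]:
    """Clonally replicated phenotypes from planted h2 and Q_ST.

    The within-population scale is fixed at one: s2_a = h2_true,
    s2_e = 1 - h2_true, and the among-cluster variance follows from
    inverting the Q_ST definition, s2_p = 2 s2_a qst_true / (1 - qst_true).
    Additive values are a ~ N(0, s2_a G); each genotype contributes
    ``n_ramets`` records sharing its genetic value with i.i.d. residuals.

    With ``exact_cluster_variance`` (the default) the handful of cluster
    effects is rescaled to carry exactly the planted among-cluster
    variance, so parameter-recovery studies measure estimation error
    rather than the chi-square(d-1) scatter of d ~ 4 draws; switch it off
    to keep the natural sampling distribution (as a null-calibration study
    must).
    """
    if cfg.qst_true >= 1:
        raise ValueError("qst_true = 1 implies infinite cluster variance")
    K = G.G if isinstance(G, RelationshipMatrix) else np.asarray(G, dtype=float)
    clusters = np.asarray(clusters)
    n = K.shape[0]
    if len(clusters) != n:
        raise ValueError("cluster labels must cover all individuals")

    s2_a = float(cfg.h2_true)
    s2_e = float(1.0 - cfg.h2_true)
    s2_p = 2.0 * s2_a * cfg.qst_true / (1.0 - cfg.qst_true)

    rng = _rng(cfg.seed, "phenotype")
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    a = U @ (np.sqrt(s2_a * w) * rng.standard_normal(n))
    levels = pd.unique(clusters)
    p_eff = rng.normal(0.0, 1.0, size=len(levels))
    if s2_p > 0 and len(levels) > 1:
        if exact_cluster_variance:
            # condition the few cluster effects on the planted variance:
            # with d ~ 4 groups the realized variance of unconditioned
            # draws is chi-square with d-1 df and would dominate recovery
            p_eff = p_eff - p_eff.mean()
            p_eff *= np.sqrt(s2_p / p_eff.var(ddof=1))
        else:
            p_eff = p_eff * np.sqrt(s2_p)
    else:
        p_eff = np.zeros(len(levels))
    p_map = {lev: p_eff[i] for i, lev in enumerate(levels)}

    rows = []
    mu = 10.0
    for i in range(n):
        base = mu + p_map[clusters[i]] + a[i]
        e = rng.normal(0.0, np.sqrt(s2_e) if s2_e > 0 else 0.0, size=cfg.n_ramets)
        for r in range(cfg.n_ramets):
            rows.append((f"ind{i}", r + 1, base + e[r]))
    phenos = pd.DataFrame(rows, columns=["genotype", "ramet", "trait"])
    truth = SimTruth(
        cluster_labels=clusters,
        variance_components={"sigma2_p": s2_p, "sigma2_a": s2_a, "sigma2_e": s2_e},
    )
    return phenos, truth


# ---------------------------------------------------------------------------
# Whole-study presets
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig, preset: str = "full") -> dict:
    """One coherent synthetic study: coordinates, climate, genotypes, traits.

    ``island`` draws island-model genotypes with demes matching the climate
    zones; ``ibd`` draws spatially autocorrelated genotypes; ``full`` is the
    island panel plus clinal loci and phenotypes (with the GRM computed from
    the neutral panel).  Returns a dict of the generated tables and the
    truth object.
    """
    from .relatedness import compute_grm

    rng = _rng(cfg.seed, "coords")
    if preset not in {"island", "ibd", "full"}:
        raise ValueError(f"unknown preset {preset!r}")

    if preset == "ibd":
        g, coords = sim_ibd_genotypes(cfg)
        climate, zones = sim_climate(coords, cfg.seed, n_zones=cfg.n_pops)
        return {"genotypes": g, "coords": coords, "climate": climate,
                "truth": SimTruth(climate_zone_labels=zones)}

    g, truth = sim_island_genotypes(cfg)
    # deme-centered coordinates so climate zones align with the demes
    ex, ey = cfg.landscape_extent
    centers_x = (np.arange(cfg.n_pops) + 0.5) * ex / cfg.n_pops
    labels = truth.cluster_labels
    coords_xy = np.column_stack([
        centers_x[labels] + rng.normal(0, ex / (6 * cfg.n_pops), len(labels)),
        rng.uniform(0, ey, len(labels)),
    ])
    coords = pd.DataFrame(coords_xy, columns=["x_km", "y_km"])
    coords.insert(0, "id", g.samples)
    climate, zones = sim_climate(coords, cfg.seed, n_zones=cfg.n_pops)
    truth.climate_zone_labels = zones

    out = {"genotypes": g, "coords": coords, "climate": climate, "truth": truth}
    if preset == "full":
        g2 = sim_clinal_loci(g, coords["x_km"].to_numpy(), cfg, truth=truth)
        out["genotypes"] = g2
        grm = compute_grm(g)  # GRM from the neutral panel
        phenos, ptruth = sim_phenotypes(grm.G, labels, cfg)
        truth.variance_components = ptruth.variance_components
        out["phenotypes"] = phenos
        out["grm"] = grm
    return out
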