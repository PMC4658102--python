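"""SNP quality control and the realized additive (genomic) relationship matrix.

The realized relationship matrix follows the VanRaden (2008) construction

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),   Z = M - P,

where ``M`` is the n x m dosage matrix (0/1/2 copies of the alternate
allele), ``P`` the row vector of doubled alternate-allele frequencies and
the sum runs over the loci used.  Allele frequencies are taken from the
observed sample; missing dosages are mean-imputed per locus (``2p``) before
centering, which is unbiased under missing-at-random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("popadapt")

__all__ = ["GenotypeMatrix", "RelationshipMatrix", "qc_filter_snps", "compute_grm"]

#: QC retention thresholds (boundary-inclusive): loci are removed when
#: MAF < 0.05, missingness > 0.10 or quality score < 0.5.
MAF_MIN = 0.05
MISSING_MAX = 0.10
QUALITY_MIN = 0.5


@dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix with per-locus metadata.

    Parameters
    ----------
    dosage
        Float array of shape (n_individuals, n_loci); values 0/1/2 count
        alternate-allele copies, NaN marks missing calls.
    loci
        DataFrame with one row per locus.  Recognised columns:
        ``id``, ``chrom``, ``pos``, ``maf``, ``missing_rate``,
        ``quality_score``.  Missing summary columns are computed from the
        dosages on demand.
    samples
        Unique individual identifiers, one per dosage row.
    """

    dosage: np.ndarray
    loci: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x loci)")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.loci) != m:
            raise ValueError(f"{len(self.loci)} locus rows for {m} dosage columns")
        if len(set(self.samples)) != n:
            raise ValueError("sample ids must be unique")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        self.loci = self.loci.reset_index(drop=True)
        if "id" not in self.loci.columns:
            self.loci["id"] = [f"snp{j}" for j in range(m)]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per locus (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to loci ``index`` (positional, order kept)."""
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            loci=self.loci.iloc[np.asarray(index)].reset_index(drop=True),
            samples=list(self.samples),
        )


@dataclass
class RelationshipMatrix:
    """Marker-based additive relationship matrix with provenance fields."""

    G: np.ndarray
    ridge_applied: float = 0.0
    loci_used: int = 0
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2 or self.G.shape[0] != self.G.shape[1]:
            raise ValueError("G must be square")
        if not np.allclose(self.G, self.G.T, atol=1e-8):
            raise ValueError("G must be symmetric")


def qc_filter_snps(g: GenotypeMatrix) -> GenotypeMatrix:
    """Filter loci on MAF, missingness and per-locus quality score.

    Retention is boundary-inclusive: a locus is kept when MAF >= 0.05,
    missing rate <= 0.10 and quality score >= 0.5 (removal criteria are
    strict inequalities).  MAF and missing rate are recomputed from the
    dosages when absent from ``g.loci``; an absent quality column passes
    every locus.  Raises ``ValueError`` if no locus survives.
    """
    maf = (
        g.loci["maf"].to_numpy(dtype=float)
        if "maf" in g.loci.columns
        else g.maf()
    )
    miss = (
        g.loci["missing_rate"].to_numpy(dtype=float)
        if "missing_rate" in g.loci.columns
        else g.missing_rate()
    )
    if "quality_score" in g.loci.columns:
        qual = g.loci["quality_score"].to_numpy(dtype=float)
    else:
        qual = np.ones(g.n_loci)

    pass_maf = maf >= MAF_MIN
    pass_miss = miss <= MISSING_MAX
    pass_qual = qual >= QUALITY_MIN
    keep = pass_maf & pass_miss & pass_qual
    if not keep.any():
        raise ValueError(
            "QC removed every locus "
            f"(failed MAF: {int((~pass_maf).sum())}, "
            f"missingness: {int((~pass_miss).sum())}, "
            f"quality: {int((~pass_qual).sum())})"
        )
    logger.info(
        "QC retained %d/%d loci (MAF fail %d, missing fail %d, quality fail %d)",
        int(keep.sum()), g.n_loci,
        int((~pass_maf).sum()), int((~pass_miss).sum()), int((~pass_qual).sum()),
    )
    return g.subset_loci(np.flatnonzero(keep))


def compute_grm(g: GenotypeMatrix, ridge_tol: float = 0.0) -> RelationshipMatrix:
    """Realized relationship matrix G = ZZ'/(2 sum p(1-p)).

    Monomorphic loci (observed frequency 0 or 1) are excluded from both the
    numerator and the denominator.  Missing dosages are mean-imputed (2p)
    per locus.  If the smallest eigenvalue of the result is below
    ``-ridge_tol`` a ridge ``1e-6 * mean(diag) * I`` is added so the matrix
    is usable as a covariance in REML; the amount is stored in
    ``ridge_applied``.
    """
    p = g.alt_freq()
    poly = (p > 0.0) & (p < 1.0) & np.isfinite(p)
    n_mono = int((~poly).sum())
    if poly.sum() < 2:
        raise ValueError(
            "zero denominator: need >= 2 polymorphic loci, "
            f"{n_mono} monomorphic of {g.n_loci}"
        )
    if n_mono:
        logger.info("compute_grm: excluded %d monomorphic loci", n_mono)

    M = g.dosage[:, poly]
    pj = p[poly]
    # mean imputation before centering == set missing residual to zero
    Z = M - 2.0 * pj
    Z[np.isnan(Z)] = 0.0
    denom = 2.0 * np.sum(pj * (1.0 - pj))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)

    ridge = 0.0
    w = np.linalg.eigvalsh(G)
    if w[0] < -ridge_tol:
        ridge = 1e-6 * float(np.mean(np.diag(G)))
        G = G + ridge * np.eye(G.shape[0])
    return RelationshipMatrix(
        G=G, ridge_applied=ridge, loci_used=int(poly.sum()), samples=list(g.samples)
    )
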