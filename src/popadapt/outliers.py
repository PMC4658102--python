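"""Per-locus F_ST, the neutral (He, F_ST) envelope and outlier detection.

Differentiation is measured with the Weir & Cockerham (1984) theta estimator
throughout — for the observed panel and for the simulated neutral loci — so
that the envelope and the data share the same sampling properties.

The neutral null emulates a symmetric island model at equilibrium through
its allele-frequency distribution: each sampled deme's frequency is drawn
from the Balding-Nichols Beta distribution around an ancestral frequency,
with the differentiation parameter calibrated by a pilot run so the
realized multi-locus theta of the *sampled* loci matches the requested mean
F_ST.  Sampled loci are then diploid HWE draws of ``genes_per_deme`` genes
per deme, exactly mirroring how the observed panel is sampled.

Outlier detection iterates simulation -> envelope -> trimming until the
flagged set stabilises, reproducing the "trimmed neutral mean" procedure
used by Fdist-style scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relatedness import GenotypeMatrix

logger = logging.getLogger("popadapt")

__all__ = [
    "FstTable",
    "Envelope",
    "weir_cockerham_fst",
    "island_null_simulate",
    "conditional_envelope",
    "detect_outliers",
    "hotspot_test",
    "pairwise_ld_r2",
]


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

@dataclass
class FstTable:
    """Per-locus Weir-Cockerham theta and expected heterozygosity.

    ``table`` has columns ``id``, ``fst``, ``he``, ``a``, ``b``, ``c``
    (the variance components of the estimator; NaN where undefined).
    The multi-locus estimate is the ratio of summed components.
    """

    table: pd.DataFrame
    populations: list
    sample_sizes: dict = field(default_factory=dict)

    @property
    def multilocus_fst(self) -> float:
        a = self.table["a"].sum(skipna=True)
        denom = (self.table["a"] + self.table["b"] + self.table["c"]).sum(skipna=True)
        return float(a / denom)

    def multilocus_over(self, mask: np.ndarray) -> float:
        """Ratio-of-sums theta restricted to loci where ``mask`` is True."""
        sub = self.table[np.asarray(mask, dtype=bool)]
        return float(sub["a"].sum() / (sub["a"] + sub["b"] + sub["c"]).sum())


def _wc_components(n, p, h):
    """Weir-Cockerham (1984) a, b, c from per-population summaries.

    Parameters are arrays of shape (..., r): ``n`` diploid sample sizes,
    ``p`` alternate-allele frequencies and ``h`` observed heterozygote
    proportions per population.  Populations with n < 2 must be masked out
    by the caller (NaN-safe handling is done there).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[-1]
    nbar = n.mean(axis=-1)
    sum_n = n.sum(axis=-1)
    nc = (sum_n - (n**2).sum(axis=-1) / sum_n) / (r - 1)
    pbar = (n * p).sum(axis=-1) / sum_n
    s2 = (n * (p - pbar[..., None]) ** 2).sum(axis=-1) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=-1) / sum_n

    a = (nbar / nc) * (
        s2
        - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c, pbar


def weir_cockerham_fst(g: GenotypeMatrix, pops) -> FstTable:
    """Per-locus theta among the populations given by label vector ``pops``.

    Loci with fewer than two populations holding >= 2 non-missing genotypes
    are skipped (components NaN, logged).  Loci monomorphic across all
    populations have an undefined theta, reported as NaN.  ``he`` is
    2*pbar*(1-pbar) from the (weighted) pooled allele frequency.
    """
    pops = np.asarray(pops)
    labels = pd.unique(pops)
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")

    m = g.n_loci
    r = len(labels)
    n = np.zeros((m, r))
    p = np.zeros((m, r))
    h = np.zeros((m, r))
    for k, lab in enumerate(labels):
        d = g.dosage[pops == lab]
        ok = ~np.isnan(d)
        n[:, k] = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p[:, k] = np.nansum(d, axis=0) / (2 * n[:, k])
            h[:, k] = np.nansum(d == 1, axis=0) / n[:, k]

    # only loci where every population is usable enter the r-pop estimator;
    # partially-covered loci are skipped rather than re-estimated over subsets
    full = (n >= 2).all(axis=1)
    skipped = int((~full).sum())
    if skipped:
        logger.info("weir_cockerham_fst: skipped %d loci with thin coverage", skipped)

    a = np.full(m, np.nan)
    b = np.full(m, np.nan)
    c = np.full(m, np.nan)
    he = np.full(m, np.nan)
    if full.any():
        aa, bb, cc, pbar = _wc_components(n[full], p[full], h[full])
        poly = (pbar > 0) & (pbar < 1)
        aa[~poly] = np.nan
        bb[~poly] = np.nan
        cc[~poly] = np.nan
        a[full], b[full], c[full] = aa, bb, cc
        he[full] = 2 * pbar * (1 - pbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b + c)
    table = pd.DataFrame(
        {"id": g.loci["id"].to_numpy(), "fst": fst, "he": he, "a": a, "b": b, "c": c}
    )
    sizes = {lab: int((pops == lab).sum()) for lab in labels}
    return FstTable(table=table, populations=list(labels), sample_sizes=sizes)


# ---------------------------------------------------------------------------
# Island-model neutral null
# ---------------------------------------------------------------------------

def _simulate_pairs(F: float, d: int, genes_per_deme: int, n_sims: int,
                    rng: np.random.Generator, he_min: float = 0.02):
    """Draw (he, fst) for ``n_sims`` neutral loci at BN strength ``F``."""
    n_dip = genes_per_deme // 2
    p0 = rng.uniform(0.01, 0.99, size=n_sims)
    if F <= 0:
        pi = np.repeat(p0[:, None], d, axis=1)
    else:
        shape = (1.0 - F) / F
        pi = rng.beta(p0[:, None] * shape, (1.0 - p0[:, None]) * shape,
                      size=(n_sims, d))
    probs = np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=-1)
    counts = rng.multinomial(n_dip, probs)  # (n_sims, d, 3) genotype counts
    phat = (counts[..., 1] + 2 * counts[..., 2]) / (2 * n_dip)
    hhat = counts[..., 1] / n_dip
    n = np.full((n_sims, d), float(n_dip))
    a, b, c, pbar = _wc_components(n, phat, hhat)
    he = 2 * pbar * (1 - pbar)
    keep = he >= he_min
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b + c)
    return pd.DataFrame({"he": he[keep], "fst": fst[keep],
                         "a": a[keep], "b": b[keep], "c": c[keep]})


def island_null_simulate(
    target_mean_fst: float,
    d: int = 4,
    genes_per_deme: int = 50,
    n_demes: int = 100,
    n_sims: int = 200_000,
    seed: int = 0,
    pilot_sims: int = 5000,
) -> pd.DataFrame:
    """Neutral (he, fst) pairs calibrated to ``target_mean_fst``.

    An exchangeable island model is represented through its equilibrium
    allele-frequency distribution: deme frequencies are Beta-distributed
    around an ancestral frequency with strength F (Balding-Nichols), and
    each of the ``d`` sampled demes contributes ``genes_per_deme`` genes as
    HWE diploids.  ``n_demes`` records the conceptual deme count of the
    model (sampled demes are exchangeable draws from it) and is carried for
    provenance.  Because the sampled multi-locus theta is not exactly the
    model F, F is calibrated with a pilot run plus secant refinement until
    the realized mean is within 5% of target.

    Returns a DataFrame with columns he, fst, a, b, c and attrs recording
    the calibration.
    """
    if not (0 < target_mean_fst < 1):
        raise ValueError("target_mean_fst must be in (0, 1)")
    if d > n_demes:
        raise ValueError("cannot sample more demes than the model holds")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def realized(F: float) -> float:
        pairs = _simulate_pairs(F, d, genes_per_deme, pilot_sims, rng)
        return float(pairs["a"].sum() / (pairs["a"] + pairs["b"] + pairs["c"]).sum())

    # pilot + secant calibration of the BN strength parameter
    F0 = target_mean_fst
    r0 = realized(F0)
    F1 = max(1e-6, F0 * target_mean_fst / max(r0, 1e-9))
    for _ in range(6):
        if abs(r0 - target_mean_fst) <= 0.05 * target_mean_fst:
            F1 = F0
            break
        r1 = realized(F1)
        if abs(r1 - target_mean_fst) <= 0.05 * target_mean_fst:
            break
        if r1 == r0:
            break
        F2 = F1 + (target_mean_fst - r1) * (F1 - F0) / (r1 - r0)
        F0, r0, F1 = F1, r1, float(np.clip(F2, 1e-6, 0.99))
    F_cal = F1

    pairs = _simulate_pairs(F_cal, d, genes_per_deme, n_sims, rng)
    pairs.attrs.update(
        target_mean_fst=target_mean_fst, F_calibrated=F_cal, d=d,
        genes_per_deme=genes_per_deme, n_demes=n_demes, seed=seed,
    )
    ach = (pairs["he"].min(), pairs["he"].max())
    if ach[1] - ach[0] < 0.3:
        logger.warning("island_null_simulate: narrow He range achieved %s", ach)
    return pairs


# ---------------------------------------------------------------------------
# Heterozygosity-conditioned envelope
# ---------------------------------------------------------------------------

@dataclass
class Envelope:
    """Quantile envelope of neutral F_ST conditioned on He."""

    he_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    ci: float
    mean_neutral_fst: float
    n_sims: int
    sim_config: dict = field(default_factory=dict)

    def bounds(self, he) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper neutral quantiles at heterozygosity ``he``.

        Linear interpolation between bin centers, flat beyond the ends.
        """
        he = np.asarray(he, dtype=float)
        lo = np.interp(he, self.he_grid, self.lower)
        hi = np.interp(he, self.he_grid, self.upper)
        return lo, hi


def conditional_envelope(sim_pairs: pd.DataFrame, ci: float = 0.99,
                         n_bins: int = 20) -> Envelope:
    """Empirical per-He-bin quantile envelope from simulated neutral pairs.

    He is partitioned into ``n_bins`` equal-count bins; within each bin the
    (1-ci)/2 and 1-(1-ci)/2 empirical F_ST quantiles are taken and attached
    to the bin's mean He.
    """
    if not (0.5 < ci < 1):
        raise ValueError("ci must be in (0.5, 1)")
    if len(sim_pairs) < 10_000 and ci >= 0.99:
        logger.warning(
            "conditional_envelope: %d pairs is thin for a %.0f%% envelope",
            len(sim_pairs), 100 * ci,
        )
    he = sim_pairs["he"].to_numpy()
    fst = sim_pairs["fst"].to_numpy()
    order = np.argsort(he, kind="stable")
    he, fst = he[order], fst[order]
    edges = np.array_split(np.arange(len(he)), n_bins)
    alpha = (1 - ci) / 2
    grid, lo, hi = [], [], []
    for idx in edges:
        if len(idx) == 0:
            continue
        grid.append(he[idx].mean())
        lo.append(np.quantile(fst[idx], alpha))
        hi.append(np.quantile(fst[idx], 1 - alpha))
    mean_fst = float(
        sim_pairs["a"].sum() / (sim_pairs["a"] + sim_pairs["b"] + sim_pairs["c"]).sum()
    ) if "a" in sim_pairs else float(np.mean(fst))
    return Envelope(
        he_grid=np.asarray(grid), lower=np.asarray(lo), upper=np.asarray(hi),
        ci=ci, mean_neutral_fst=mean_fst, n_sims=len(sim_pairs),
        sim_config=dict(sim_pairs.attrs),
    )


# ---------------------------------------------------------------------------
# Iterative trimmed outlier detection
# ---------------------------------------------------------------------------

def detect_outliers(
    obs: FstTable,
    d: int = 4,
    genes_per_deme: int = 50,
    n_demes: int = 100,
    n_sims: int = 200_000,
    ci: float = 0.99,
    max_rounds: int = 5,
    seed: int = 0,
) -> dict:
    """Iteratively trimmed Fdist-style outlier scan.

    Each round simulates the neutral null at the current neutral mean F_ST,
    builds the He-conditioned envelope, flags observed loci outside it and
    recomputes the mean over unflagged loci; rounds repeat until the flag
    set is stable or ``max_rounds``.  High-side flags are candidates for
    diversifying selection, low-side flags for balancing selection.

    Returns a dict with keys ``flags`` (DataFrame id/fst/he/flag),
    ``neutral_fst`` (per-locus F_ST of unflagged loci, the input to the
    Q_ST-F_ST neutrality null), ``mean_neutral_fst``, ``envelope``,
    ``converged`` and ``n_rounds``.
    """
    tab = obs.table
    valid = tab["fst"].notna().to_numpy()
    if not valid.any():
        raise ValueError("no defined per-locus F_ST values")

    flagged = np.zeros(len(tab), dtype=bool)
    env = None
    converged = False
    n_rounds = 0
    for rnd in range(max_rounds):
        n_rounds = rnd + 1
        mean_fst = obs.multilocus_over(valid & ~flagged)
        mean_fst = max(mean_fst, 1e-4)  # BN strength must stay positive
        pairs = island_null_simulate(
            mean_fst, d=d, genes_per_deme=genes_per_deme, n_demes=n_demes,
            n_sims=n_sims, seed=seed + rnd,
        )
        env = conditional_envelope(pairs, ci=ci)
        env.mean_neutral_fst = mean_fst
        lo, hi = env.bounds(tab["he"].to_numpy())
        high = valid & (tab["fst"].to_numpy() > hi)
        low = valid & (tab["fst"].to_numpy() < lo)
        new_flagged = high | low
        if np.array_equal(new_flagged, flagged) and rnd > 0:
            converged = True
            break
        flagged = new_flagged
    else:
        logger.warning("detect_outliers: flag set not stable after %d rounds", max_rounds)

    lo, hi = env.bounds(tab["he"].to_numpy())
    flag = np.where(
        valid & (tab["fst"].to_numpy() > hi), "high",
        np.where(valid & (tab["fst"].to_numpy() < lo), "low", ""),
    )
    flags = pd.DataFrame(
        {"id": tab["id"], "fst": tab["fst"], "he": tab["he"], "flag": flag}
    )
    neutral_mask = valid & (flag == "")
    return {
        "flags": flags,
        "neutral_fst": tab.loc[neutral_mask, "fst"].to_numpy(),
        "mean_neutral_fst": obs.multilocus_over(neutral_mask),
        "envelope": env,
        "converged": converged,
        "n_rounds": n_rounds,
    }


# ---------------------------------------------------------------------------
# Chromosome hotspot test
# ---------------------------------------------------------------------------

def hotspot_test(outlier_chroms, n_chromosomes: int, n_perm: int = 1000,
                 seed: int = 0) -> dict:
    """Goodness-of-fit and randomization test for outlier clustering.

    ``outlier_chroms`` are chromosome labels (1..n_chromosomes or strings)
    of the outlier loci.  The chi-square GOF compares per-chromosome counts
    to a uniform expectation (df = n_chromosomes - 1).  The randomization
    scatters the same total uniformly ``n_perm`` times and records the
    maximum per-chromosome count of each replicate; a chromosome is a
    hotspot when its observed count reaches the maximum count seen across
    all replicates.
    """
    chroms = pd.Series(list(outlier_chroms))
    if len(chroms) == 0:
        raise ValueError("no outliers supplied")
    counts = chroms.value_counts()
    if len(counts) > n_chromosomes:
        raise ValueError("more chromosome labels than n_chromosomes")
    labels = sorted(counts.index.tolist(), key=str)
    # chromosomes carrying no outlier still enter the uniform expectation
    pad = [f"(no-outlier chromosome {i + 1})"
           for i in range(n_chromosomes - len(labels))]
    full = pd.Series(0.0, index=labels + pad)
    full.loc[counts.index] = counts.values.astype(float)
    observed = full.to_numpy()

    total = int(observed.sum())
    chi2, p_chi2 = stats.chisquare(observed)  # uniform expectation
    df = n_chromosomes - 1

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scatter = rng.multinomial(total, np.full(n_chromosomes, 1.0 / n_chromosomes),
                              size=n_perm)
    max_per_rep = scatter.max(axis=1)
    threshold = int(max_per_rep.max())
    hotspots = full[full >= threshold].index.tolist()
    return {
        "chi2": float(chi2),
        "df": int(df),
        "p": float(p_chi2),
        "threshold": threshold,
        "hotspots": hotspots,
        "counts": full,
    }


# ---------------------------------------------------------------------------
# Pairwise LD among loci
# ---------------------------------------------------------------------------

def pairwise_ld_r2(g: GenotypeMatrix, locus_index) -> pd.DataFrame:
    """Composite (genotypic) r-squared between the selected loci.

    Squared Pearson correlation of dosages over individuals with pairwise-
    complete observations; rows/columns for monomorphic loci are NaN.
    """
    idx = np.asarray(locus_index)
    ids = g.loci["id"].iloc[idx].tolist()
    d = pd.DataFrame(g.dosage[:, idx], columns=ids)
    mono = d.nunique(dropna=True) <= 1
    r2 = d.corr() ** 2
    np.fill_diagonal(r2.values, 1.0)
    r2.loc[mono, :] = np.nan
    r2.loc[:, mono] = np.nan
    return r2
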