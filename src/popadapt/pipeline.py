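"""End-to-end orchestration of the inference chain on one dataset.

simulate -> QC -> GRM -> climate clustering -> Q_ST / h2 / P_ST ->
F_ST outliers (trimmed envelope) -> neutrality test -> SPA cline scores ->
SAM environment scan -> multi-evidence adaptive-SNP report.

The function operates on a synthetic study from :mod:`popadapt.simulate`
(where the truth is known) but every stage consumes only the observable
tables, so the same chain applies to real inputs loaded through
:mod:`popadapt.io`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .climate import kmedoids_ch, sam_scan
from .integrate import adaptive_snp_report, method_overlap
from .mixedmodel import animal_model_spec, h2_pst, narrow_qst, reml_fit
from .neutrality import neutrality_pvalue, simulate_neutral_null
from .outliers import detect_outliers, weir_cockerham_fst
from .relatedness import compute_grm, qc_filter_snps
from .simulate import SimConfig, simulate_dataset
from .spatial import spa_cline_scores

logger = logging.getLogger("popadapt")


def run_pipeline(
    cfg: SimConfig,
    outdir: Path | None = None,
    n_sims_null: int = 20_000,
    n_reps_neutrality: int = 20_000,
    k_range=range(2, 7),
) -> dict:
    """Run the full chain on one simulated study; return a summary dict."""
    data = simulate_dataset(cfg, preset="full")
    g = data["genotypes"]
    truth = data["truth"]

    g_qc = qc_filter_snps(g)
    grm = compute_grm(g_qc)

    clustering = kmedoids_ch(data["climate"], k_range, seed=cfg.seed)
    clusters = clustering.labels
    d = clustering.K

    # per-genotype records with ramet replication share the genotype index
    ph = data["phenotypes"]
    gmap = {s: i for i, s in enumerate(g.samples)}
    gi = ph["genotype"].map(gmap).to_numpy()
    y = ph["trait"].to_numpy(dtype=float)
    rec_clusters = clusters[gi]
    vc = reml_fit(animal_model_spec(y, rec_clusters, grm, genotype_index=gi))
    qst = narrow_qst(vc, d=d)
    h2, pst, _, _ = h2_pst(y, grm, rec_clusters, genotype_index=gi)

    obs_fst = weir_cockerham_fst(g_qc, clusters)
    scan = detect_outliers(obs_fst, d=d, n_sims=n_sims_null, seed=cfg.seed)
    fst_high = set(scan["flags"].loc[scan["flags"]["flag"] == "high", "id"])

    null = simulate_neutral_null(scan["neutral_fst"], vc, d=d,
                                 n_reps=n_reps_neutrality, seed=cfg.seed)
    mean_neutral = float(np.mean(scan["neutral_fst"]))
    p_neutrality = neutrality_pvalue(qst, null, mean_neutral)

    spa_geo = spa_cline_scores(g_qc, data["coords"][["x_km", "y_km"]].to_numpy())
    spa_clim = spa_cline_scores(
        g_qc, data["climate"][["MAT", "NFFD", "MAP"]].to_numpy()
    )
    spa_geo_set = set(spa_geo.loc[spa_geo["flag_5pct"], "id"])
    spa_clim_set = set(spa_clim.loc[spa_clim["flag_5pct"], "id"])

    sam = sam_scan(g_qc, data["climate"], clusters=clusters)
    sam_set = set(sam.loc[sam["pass"], "id"])

    overlap = method_overlap({
        "fst_climate": fst_high,
        "spa_geography": spa_geo_set,
        "spa_climate": spa_clim_set,
        "sam": sam_set,
    })

    # association table: the planted clinal loci "underlie" the trait
    assoc = pd.DataFrame({
        "snp_id": truth.clinal_locus_ids,
        "trait": "trait",
        "p_value": 1e-6,
        "source": "synthetic-gwas",
    })
    verdicts = {"trait": p_neutrality < 0.05}
    report = adaptive_snp_report(
        assoc, verdicts,
        {"fst_climate": fst_high, "spa_geography": spa_geo_set,
         "spa_climate": spa_clim_set, "sam": sam_set},
        known_snps=set(g_qc.loci["id"]),
    )

    summary = {
        "n_individuals": g.n_individuals,
        "n_loci_qc": g_qc.n_loci,
        "K_selected": d,
        "h2": h2.value, "qst": qst.value, "pst": pst.value,
        "p_neutrality": p_neutrality,
        "mean_fst_all": obs_fst.multilocus_fst,
        "mean_neutral_fst": scan["mean_neutral_fst"],
        "n_fst_outliers": len(fst_high),
        "n_sam_hits": len(sam_set),
        "n_adaptive_snps": len(report),
        "overlap_fraction_snps": overlap["overlap_fraction_snps"],
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_genotypes_tsv(g, outdir / "genotypes.tsv")
        data["climate"].to_csv(outdir / "climate.csv", index=False)
        data["coords"].to_csv(outdir / "coords.csv", index=False)
        ph.to_csv(outdir / "phenotypes.csv", index=False)
        pd.DataFrame({"id": g.samples, "cluster": clusters}).to_csv(
            outdir / "clusters.csv", index=False)
        scan["flags"].to_csv(outdir / "fst_flags.tsv", sep="\t", index=False)
        sam.to_csv(outdir / "sam.tsv", sep="\t", index=False)
        report.to_csv(outdir / "adaptive_snps.tsv", sep="\t", index=False)
        pio.write_truth(truth, outdir / "truth.json")
    return summary
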