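"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as an individuals x loci TSV of 0/1/2 dosages
(first column the individual id, ``NA`` for missing) or as a minimal VCF
with diploid GT fields (``./.`` = missing), read through cyvcf2.  All
tabular side data (phenotypes, climate, coordinates, cluster labels,
association tables) are plain CSV/TSV via pandas; the relationship matrix
is a TSV with ids plus a JSON sidecar carrying provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .relatedness import GenotypeMatrix, RelationshipMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_grm",
    "write_grm",
    "write_truth",
]


def read_genotypes(path) -> GenotypeMatrix:
    """Load genotypes from a ``.vcf`` or a dosage ``.tsv`` file."""
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_tsv(path)


def _read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosage = df.to_numpy(dtype=float)
    loci = pd.DataFrame({"id": df.columns.astype(str)})
    return GenotypeMatrix(dosage=dosage, loci=loci, samples=[str(s) for s in df.index])


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    for var in vcf:
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS))
    dosage = np.array(rows).T if rows else np.empty((len(samples), 0))
    loci = pd.DataFrame(meta, columns=["id", "chrom", "pos"])
    return GenotypeMatrix(dosage=dosage, loci=loci, samples=samples)


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosage, index=g.samples, columns=g.loci["id"])
    df.index.name = "id"
    out = df.astype("Int64")
    out.to_csv(path, sep="\t", na_rep="NA")


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal VCF: CHROM, POS, ID, REF=A, ALT=C and GT-only samples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        chrom = g.loci["chrom"] if "chrom" in g.loci.columns else ["1"] * g.n_loci
        pos = g.loci["pos"] if "pos" in g.loci.columns else range(1, g.n_loci + 1)
        for j, (c, p, lid) in enumerate(zip(chrom, pos, g.loci["id"])):
            gts = "\t".join(
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosage[:, j]
            )
            fh.write(f"{c}\t{p}\t{lid}\tA\tC\t.\t.\t.\tGT\t{gts}\n")


def write_grm(grm: RelationshipMatrix, prefix) -> None:
    prefix = Path(prefix)
    df = pd.DataFrame(grm.G, index=grm.samples or None,
                      columns=grm.samples or None)
    df.to_csv(prefix.with_suffix(".grm.tsv"), sep="\t")
    sidecar = {"loci_used": grm.loci_used, "ridge_applied": grm.ridge_applied}
    prefix.with_suffix(".grm.json").write_text(json.dumps(sidecar, indent=1))


def read_grm(prefix) -> RelationshipMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".grm.tsv"), sep="\t", index_col=0)
    side = json.loads(prefix.with_suffix(".grm.json").read_text())
    return RelationshipMatrix(G=df.to_numpy(dtype=float),
                              ridge_applied=side.get("ridge_applied", 0.0),
                              loci_used=side.get("loci_used", 0),
                              samples=[str(s) for s in df.index])


def write_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))
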