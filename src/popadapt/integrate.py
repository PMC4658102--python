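"""Multi-evidence integration: outlier methods x trait associations.

Combines the per-method outlier flag sets, externally supplied SNP-trait
association tables and the per-trait Q_ST neutrality verdicts into the
final adaptive-SNP report: a SNP is called adaptive when at least one
outlier method flags it *and* it is associated with at least one trait
whose Q_ST departed from the neutral expectation.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("popadapt")

__all__ = ["method_overlap", "adaptive_snp_report", "outlier_assoc_correlation"]


def method_overlap(flag_sets: dict) -> dict:
    """Venn cell counts and per-method sharing for named outlier sets.

    Returns ``cells`` mapping a '&'-joined method combination to the count
    of SNPs flagged by exactly that combination, and ``shared_fraction``
    mapping each method to the fraction of its SNPs flagged by at least one
    other method.  Because the spirit of "percent overlap" admits two
    denominators, both are reported: ``overlap_fraction_snps`` (shared SNPs
    over the union) and ``overlap_fraction_method_snp`` (shared method-SNP
    pairs over all method-SNP pairs).
    """
    if len(flag_sets) < 2:
        raise ValueError("need >= 2 named sets")
    names = list(flag_sets)
    sets = {k: set(v) for k, v in flag_sets.items()}
    universe = set().union(*sets.values())

    cells = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in names if c not in combo)) \
                if len(combo) < len(names) else set()
            cells["&".join(combo)] = len(inside - outside)

    shared = {}
    for m in names:
        others = set().union(*(sets[o] for o in names if o != m))
        shared[m] = (len(sets[m] & others) / len(sets[m])) if sets[m] else 0.0

    shared_snps = {s for s in universe
                   if sum(s in sets[m] for m in names) >= 2}
    pair_total = sum(len(sets[m]) for m in names)
    pair_shared = sum(len(sets[m] & shared_snps) for m in names)
    return {
        "cells": cells,
        "shared_fraction": shared,
        "overlap_fraction_snps": len(shared_snps) / len(universe) if universe else 0.0,
        "overlap_fraction_method_snp": pair_shared / pair_total if pair_total else 0.0,
        "n_union": len(universe),
    }


def adaptive_snp_report(
    assoc: pd.DataFrame,
    trait_verdicts: dict,
    outlier_flags: dict,
    known_snps=None,
    annotations: dict | None = None,
) -> pd.DataFrame:
    """Adaptive-SNP table from outlier flags, associations and verdicts.

    ``assoc`` needs columns ``snp_id``, ``trait`` (and optionally
    ``p_value``, ``source``); ``trait_verdicts`` maps every trait appearing
    in ``assoc`` to its adaptive flag; ``outlier_flags`` maps method name
    to a set of SNP ids.  SNPs absent from ``known_snps`` (when given) are
    excluded as orphans.  The report keeps SNPs flagged by >= 1 method and
    associated with >= 1 adaptive trait, recording the flagging method set,
    whether the SNP is shared (>= 2 methods) or unique, the adaptive-trait
    subset and the pleiotropy degree (its cardinality).
    """
    missing = set(assoc["trait"]) - set(trait_verdicts)
    if missing:
        raise ValueError(f"verdicts missing for traits: {sorted(missing)}")
    if assoc.empty:
        return _empty_report()

    assoc = assoc.copy()
    if known_snps is not None:
        known = set(known_snps)
        orphans = sorted(set(assoc["snp_id"]) - known)
        if orphans:
            logger.info("adaptive_snp_report: excluded %d orphan SNP ids",
                        len(orphans))
            assoc = assoc[assoc["snp_id"].isin(known)]

    flagged_by = {}
    for method, ids in outlier_flags.items():
        for s in ids:
            flagged_by.setdefault(s, set()).add(method)

    rows = []
    for snp, sub in assoc.groupby("snp_id", sort=True):
        methods = flagged_by.get(snp, set())
        if not methods:
            continue
        traits = sorted(set(sub["trait"]))
        adaptive = [t for t in traits if trait_verdicts[t]]
        if not adaptive:
            continue
        rows.append({
            "snp_id": snp,
            "methods": ";".join(sorted(methods)),
            "n_methods": len(methods),
            "shared": len(methods) >= 2,
            "traits": ";".join(traits),
            "adaptive_traits": ";".join(adaptive),
            "pleiotropy": len(adaptive),
            "annotation": (annotations or {}).get(snp, ""),
        })
    return pd.DataFrame(rows) if rows else _empty_report()


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "snp_id", "methods", "n_methods", "shared", "traits",
        "adaptive_traits", "pleiotropy", "annotation",
    ])


def outlier_assoc_correlation(n_outlier_assoc, n_assoc) -> dict:
    """Pearson correlation across traits of outlier-linked vs total SNPs.

    ``n_outlier_assoc[t]`` counts the outlier SNPs associated with trait t,
    ``n_assoc[t]`` all SNPs associated with it.  Requires >= 5 traits and
    non-degenerate counts.
    """
    x = np.asarray(n_outlier_assoc, dtype=float)
    y = np.asarray(n_assoc, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need matched counts for >= 5 traits")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in counts")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n_traits": len(x)}
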