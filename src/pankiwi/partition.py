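"""Gene-family occupancy partitioning and set-based family screens.

A family's *frequency* is the number of assemblies carrying at least one
member gene; copy number plays no role in classification. The four
occupancy categories (core / softcore / dispensable / cloud) are defined
by :class:`~pankiwi.model.PartitionThresholds`: with N = 15 assemblies
the default 85% softcore floor gives the bands N=15, 13-14, 2-12, 1.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import (
    CATEGORIES,
    FamilyMatrix,
    PartitionResult,
    PartitionThresholds,
    round_half_up,
)


def classify_families(matrix: FamilyMatrix,
                      thresholds: PartitionThresholds | None = None) -> PartitionResult:
    """Assign every family to exactly one occupancy category.

    Gene counts per category sum each family's members over *all*
    assemblies where present (a family's genes travel with its category).
    Per-assembly composition counts the genes each assembly contributes
    to each category.
    """
    if thresholds is None:
        thresholds = PartitionThresholds(matrix.n_assemblies)
    if thresholds.n_assemblies != matrix.n_assemblies:
        raise ValueError(
            f"thresholds are for N={thresholds.n_assemblies} but the matrix has "
            f"{matrix.n_assemblies} assemblies"
        )
    if len(matrix.family_ids) == 0:
        raise ValueError("empty family matrix")
    freqs = matrix.frequencies()
    cats = freqs.map(thresholds.category_of)
    cats.name = "category"

    family_counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    totals = matrix.gene_totals()
    gene_counts = {c: int(totals[cats == c].sum()) for c in CATEGORIES}
    per_assembly = pd.DataFrame(
        {
            c: matrix.counts.loc[cats == c].sum(axis=0)
            for c in CATEGORIES
        }
    )
    return PartitionResult(cats, family_counts, gene_counts, per_assembly)


def summary_from_counts(family_counts: Mapping[str, int],
                        gene_counts: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Composition table from per-category counts: counts, percentages
    (half-up, 2 decimals) and a totals row."""
    rows = []
    fam_total = sum(family_counts.values())
    gene_total = sum(gene_counts.values()) if gene_counts else None
    for c in CATEGORIES:
        nf = int(family_counts.get(c, 0))
        row = {
            "category": c,
            "n_families": nf,
            "family_pct": round_half_up(100.0 * nf / fam_total) if fam_total else float("nan"),
        }
        if gene_counts is not None:
            ng = int(gene_counts.get(c, 0))
            row["n_genes"] = ng
            row["gene_pct"] = (
                round_half_up(100.0 * ng / gene_total) if gene_total else float("nan")
            )
        rows.append(row)
    total_row = {"category": "total", "n_families": fam_total, "family_pct": 100.0}
    if gene_counts is not None:
        total_row["n_genes"] = gene_total
        total_row["gene_pct"] = 100.0
    rows.append(total_row)
    return pd.DataFrame(rows)


def partition_summary(result: PartitionResult) -> pd.DataFrame:
    return summary_from_counts(result.family_counts, result.gene_counts)


def category_share(counts: Mapping[str, int], categories: Iterable[str]) -> float:
    """Combined percentage (half-up, 2 decimals) of the given categories,
    computed on raw counts so pooled shares do not accumulate per-category
    rounding error."""
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    part = sum(int(counts.get(c, 0)) for c in categories)
    return round_half_up(100.0 * part / total)


def group_specific_families(matrix: FamilyMatrix,
                            groups: Mapping[str, str],
                            focal: str) -> list[str]:
    """Families present in *every* focal-group assembly and absent from
    *every* other assembly. ``groups`` maps assembly -> group label."""
    focal_asm = [a for a in matrix.assembly_ids if groups.get(a) == focal]
    other_asm = [a for a in matrix.assembly_ids if groups.get(a) != focal]
    if not focal_asm:
        raise ValueError(f"focal group {focal!r} has no assemblies")
    present = (matrix.counts[focal_asm] >= 1).all(axis=1)
    if other_asm:
        absent = (matrix.counts[other_asm] == 0).all(axis=1)
    else:
        absent = pd.Series(True, index=matrix.counts.index)
    return list(matrix.counts.index[present & absent])


def presence_only_in_sex(matrix: FamilyMatrix,
                         sex: Mapping[str, str],
                         target_sex: str) -> list[str]:
    """Families found in each assembly of one sex and no assembly of the
    other — the sex-linked family screen (alias of the group screen)."""
    return group_specific_families(matrix, sex, target_sex)


def enrichment_test(hits: Iterable[str],
                    annotation: Mapping[str, Iterable[str]],
                    universe: Iterable[str],
                    min_hits: int = 2) -> pd.DataFrame:
    """Over-representation test per term.

    ``annotation`` maps gene -> terms. For each term with at least
    ``min_hits`` hit genes, the one-sided hypergeometric upper-tail
    p-value of the 2x2 table (hits x annotated, within the universe) is
    computed, then Benjamini-Hochberg corrected across tested terms.
    Terms below ``min_hits`` are reported with NA p/q.
    """
    universe_set = set(universe)
    hit_set = set(hits) & universe_set
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene not in universe_set:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)

    rows = []
    for term in sorted(term_genes):
        annotated = term_genes[term]
        k = len(hit_set & annotated)
        rows.append(
            {
                "term": term,
                "n_hits": k,
                "n_annotated": len(annotated),
                "n_universe": len(universe_set),
                "n_query": len(hit_set),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "n_hits", "n_annotated",
                                     "n_universe", "n_query"])
    if df.empty:
        df["p"] = []
        df["q"] = []
        return df
    tested = df["n_hits"] >= min_hits
    pvals = np.full(len(df), np.nan)
    for i in df.index[tested]:
        k = df.at[i, "n_hits"]
        K = df.at[i, "n_annotated"]
        M = df.at[i, "n_universe"]
        n = df.at[i, "n_query"]
        pvals[i] = hypergeom.sf(k - 1, M, K, n)
    df["p"] = pvals
    qvals = np.full(len(df), np.nan)
    if tested.any():
        qvals[tested.to_numpy()] = multipletests(
            pvals[tested.to_numpy()], method="fdr_bh"
        )[1]
    df["q"] = qvals
    return df


def absent_in_target(matrix: FamilyMatrix,
                     target_assemblies: Sequence[str],
                     category: str | None = None,
                     thresholds: PartitionThresholds | None = None) -> list[str]:
    """Families with zero genes in every target assembly but present
    somewhere else; optionally restricted to one occupancy category."""
    missing = set(target_assemblies) - set(matrix.assembly_ids)
    if missing:
        raise KeyError(f"unknown assemblies: {sorted(missing)}")
    others = [a for a in matrix.assembly_ids if a not in set(target_assemblies)]
    absent = (matrix.counts[list(target_assemblies)] == 0).all(axis=1)
    present_elsewhere = (matrix.counts[others] >= 1).any(axis=1) if others else False
    sel = matrix.counts.index[absent & present_elsewhere]
    if category is not None:
        cats = classify_families(matrix, thresholds).categories
        sel = [f for f in sel if cats[f] == category]
    return list(sel)
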