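"""Resistance gene analog (RGA) atlas: physical clustering of gene
families, divergent paired-NLR detection, per-class summaries and the
pan-RGA occupancy partition.

RGA class labels (NBS / RLK / RLP / TM-CC) are consumed as annotations
produced upstream (e.g. by domain-based classifiers); no domain
prediction happens here.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd

from .model import (
    CATEGORIES,
    FamilyMatrix,
    Gene,
    GeneSet,
    PartitionResult,
    PartitionThresholds,
    round_half_up,
)
from .partition import classify_families, partition_summary

# re-exported here because the absent-family screen is an RGA workflow
from .partition import absent_in_target  # noqa: F401


def cluster_genes(genes: GeneSet, max_gap: int = 200_000,
                  method: str = "chain") -> list[list[Gene]]:
    """Physical clusters of same-family genes on a chromosome.

    ``chain`` (default): single-linkage on successive genes sorted by
    start — a gene joins the open cluster when the gap to the cluster's
    rightmost end so far is <= ``max_gap`` (gap = next.start - prev_end
    - 1, floored at 0 for overlaps), so a chain of 150-kb gaps stays one
    cluster even when its ends lie further apart. ``all-pairs`` instead
    requires every member within ``max_gap`` of the seed span. Only
    clusters of >= 2 genes are returned; genes without a family_id are
    skipped with a warning.
    """
    if method not in ("chain", "all-pairs"):
        raise ValueError("method must be 'chain' or 'all-pairs'")
    skipped = [g.id for g in genes if g.family_id is None]
    if skipped:
        warnings.warn(
            f"{len(skipped)} genes lack family_id and were skipped from clustering",
            stacklevel=2,
        )
    by_key: dict[tuple[str, str], list[Gene]] = {}
    for g in genes:
        if g.family_id is None:
            continue
        by_key.setdefault((g.chrom, g.family_id), []).append(g)

    clusters: list[list[Gene]] = []
    for key in sorted(by_key):
        members = sorted(by_key[key], key=lambda g: (g.start, g.end, g.id))
        current = [members[0]]
        right_end = members[0].end
        for g in members[1:]:
            gap = max(g.start - right_end - 1, 0)
            near = gap <= max_gap
            if method == "all-pairs" and near:
                near = all(
                    max(g.start - m.end - 1, 0) <= max_gap for m in current
                )
            if near:
                current.append(g)
                right_end = max(right_end, g.end)
            else:
                if len(current) >= 2:
                    clusters.append(current)
                current = [g]
                right_end = g.end
        if len(current) >= 2:
            clusters.append(current)
    return clusters


def clustered_fraction(genes: GeneSet, clusters: Sequence[Sequence[Gene]],
                       rga_class: str) -> float:
    """Percent of genes of one RGA class that sit in size->=2 clusters."""
    class_genes = {g.id for g in genes if g.rga_class == rga_class}
    if not class_genes:
        return float("nan")
    in_clusters = {g.id for cl in clusters for g in cl}
    return round_half_up(100.0 * len(class_genes & in_clusters) / len(class_genes))


def paired_nlr(genes: GeneSet, max_gap: int = 20_000) -> list[dict]:
    """Divergent head-to-head NLR pairs among NBS genes.

    A pair is two NBS genes adjacent in the NBS-only order on a
    chromosome (no NBS gene between them), with strands (-,+) in
    coordinate order — transcription pointing apart, promoters facing —
    and an intergenic gap <= ``max_gap``. Pairing is greedy left-to-
    right; each gene joins at most one pair. Genes lacking strand are an
    error here (orientation is the definition).
    """
    nbs = [g for g in genes if g.rga_class == "NBS"]
    bad = [g.id for g in nbs if g.strand not in ("+", "-")]
    if bad:
        raise ValueError(f"NBS genes without strand: {bad[:5]}")
    by_chrom: dict[str, list[Gene]] = {}
    for g in nbs:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs: list[dict] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.id))
        i = 0
        while i < len(ordered) - 1:
            left, right = ordered[i], ordered[i + 1]
            gap = max(right.start - left.end - 1, 0)
            if left.strand == "-" and right.strand == "+" and gap <= max_gap:
                pairs.append(
                    {
                        "chrom": chrom,
                        "left": left.id,
                        "right": right.id,
                        "gap": gap,
                    }
                )
                i += 2  # greedy: both genes consumed
            else:
                i += 1
    return pairs


def paired_nlr_rates(genes: GeneSet, pairs: Sequence[Mapping]) -> dict[str, float]:
    """Both readings of 'percent paired NLRs of NBS genes': genes in
    pairs / NBS genes, and pairs / NBS genes."""
    n_nbs = len(genes.of_class("NBS"))
    if n_nbs == 0:
        return {"genes_in_pairs_pct": float("nan"), "pairs_per_nbs_pct": float("nan")}
    return {
        "genes_in_pairs_pct": round_half_up(100.0 * 2 * len(pairs) / n_nbs),
        "pairs_per_nbs_pct": round_half_up(100.0 * len(pairs) / n_nbs),
    }


def pan_rga(matrix: FamilyMatrix,
            thresholds: PartitionThresholds | None = None,
            class_of_family: Mapping[str, str] | None = None
            ) -> tuple[PartitionResult, pd.DataFrame]:
    """Occupancy partition of an RGA-restricted family matrix.

    Delegates to the pan-genome classifier; additionally, when a family
    -> RGA-class map is given, reports per-class occupancy gene
    percentages (each RGA class split into core/softcore/dispensable/
    cloud shares).
    """
    result = classify_families(matrix, thresholds)
    if class_of_family is None:
        per_class = pd.DataFrame()
    else:
        totals = matrix.gene_totals()
        rows = []
        classes = sorted(set(class_of_family.values()))
        for cls in classes:
            fams = [f for f in matrix.family_ids if class_of_family.get(f) == cls]
            cls_total = int(totals[fams].sum())
            row = {"rga_class": cls, "n_genes": cls_total}
            for cat in CATEGORIES:
                cat_genes = int(
                    totals[[f for f in fams if result.categories[f] == cat]].sum()
                )
                row[f"{cat}_pct"] = (
                    round_half_up(100.0 * cat_genes / cls_total)
                    if cls_total else float("nan")
                )
            rows.append(row)
        per_class = pd.DataFrame(rows)
    return result, per_class


def pan_rga_summary(result: PartitionResult) -> pd.DataFrame:
    return partition_summary(result)
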