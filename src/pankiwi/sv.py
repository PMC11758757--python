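"""Structural-variant landscape analytics.

Covers genic-context annotation of SVs, sliding-window density scans
with percentile-threshold hotspot calling, per-group allele frequencies,
the group-favored SV screen (frequency > 0.5 in the focal group, < 0.05
in every other group), gene classification against hotspot regions, and
PLINK-style genotype-level filtering (--geno / --maf analogues).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    GeneSet,
    GroupAssignment,
    RegionSet,
    VariantCohort,
    WindowTrack,
    round_half_up,
    tile_windows,
)
from .popgen import call_percentile_regions

CONTEXT_PRECEDENCE = ("exon", "intron", "upstream", "downstream", "intergenic")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def annotate_sv_context(cohort: VariantCohort, genes: GeneSet,
                        flank: int = 1000) -> pd.Series:
    """Genic-context category per variant.

    Precedence exon > intron > upstream > downstream > intergenic; a
    variant overlapping any exon anywhere is 'exon' even if it also sits
    upstream of another gene. Upstream/downstream are ``flank``-bp
    strand-aware windows. Deletions and inversions overlap with their
    full span; insertions with their single anchor base. When no gene
    carries exon features, body overlaps collapse to 'genic'.
    """
    have_exons = genes.has_exons()
    if not have_exons and len(genes) > 0:
        warnings.warn(
            "GeneSet has no exon features; exon/intron collapse to 'genic'",
            stacklevel=2,
        )
    by_chrom = genes.by_chrom()
    rank = {c: i for i, c in enumerate(CONTEXT_PRECEDENCE)}
    rank["genic"] = rank["intron"]  # body hit without exon models
    labels = []
    for v in cohort.records:
        s, e = v.span()
        best = "intergenic"
        for g in by_chrom.get(v.chrom, []):
            cand = None
            if _overlap(s, e, g.start, g.end):
                if have_exons:
                    if g.exons and any(_overlap(s, e, xs, xe) for xs, xe in g.exons):
                        cand = "exon"
                    else:
                        cand = "intron"
                else:
                    cand = "genic"
            else:
                up = g.upstream_window(flank)
                down = g.downstream_window(flank)
                if up and _overlap(s, e, *up):
                    cand = "upstream"
                elif down and _overlap(s, e, *down):
                    cand = "downstream"
            if cand is not None and rank[cand] < rank[best]:
                best = cand
            if best == "exon":
                break
        labels.append(best)
    ids = [v.id or f"var{i + 1}" for i, v in enumerate(cohort.records)]
    return pd.Series(labels, index=ids, name="context")


def context_summary(contexts: pd.Series) -> pd.DataFrame:
    """Category percentage table (half-up, 2 decimals)."""
    counts = contexts.value_counts()
    total = int(counts.sum())
    rows = [
        {
            "context": c,
            "n": int(counts.get(c, 0)),
            "pct": round_half_up(100.0 * counts.get(c, 0) / total) if total else float("nan"),
        }
        for c in list(CONTEXT_PRECEDENCE) + ["genic"]
        if c in counts or c in CONTEXT_PRECEDENCE
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hotspot scan
# ---------------------------------------------------------------------------


def sv_window_counts(cohort: VariantCohort,
                     window: int = 100_000,
                     step: int = 20_000,
                     chrom_lengths: Mapping[str, int] | None = None,
                     by: str = "start") -> WindowTrack:
    """Per-window SV counts in sliding windows.

    ``by='start'`` (default) counts a variant in every window containing
    its start position — each interior variant lands in window/step
    windows; ``by='overlap'`` counts any span overlap.
    """
    if by not in ("start", "overlap"):
        raise ValueError("by must be 'start' or 'overlap'")
    pos = np.array([v.pos for v in cohort.records], dtype=np.int64)
    ends = np.array([v.span()[1] for v in cohort.records], dtype=np.int64)
    chrom = np.array([v.chrom for v in cohort.records])
    chroms = cohort.chroms() or list(chrom_lengths or {})
    rows = []
    for ch in chroms:
        mask = chrom == ch
        length = (chrom_lengths or {}).get(
            ch, int(ends[mask].max()) if mask.any() else 1
        )
        p_ch, e_ch = pos[mask], ends[mask]
        for ws, we in tile_windows(length, window, step):
            if by == "start":
                n = int(((p_ch >= ws) & (p_ch <= we)).sum())
            else:
                n = int(((p_ch <= we) & (e_ch >= ws)).sum())
            rows.append((ch, ws, we, float(n), n))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_sites"])
    return WindowTrack(df, window, step)


def call_sv_hotspots(track: WindowTrack, percentile: float = 95.0) -> RegionSet:
    """Merge the top-(100-percentile)% densest windows into hotspot
    regions — same strict-threshold machinery as HDR calling."""
    return call_percentile_regions(track, percentile)


# ---------------------------------------------------------------------------
# group frequencies and the favored-SV screen
# ---------------------------------------------------------------------------


def group_sv_frequencies(cohort: VariantCohort,
                         groups: GroupAssignment,
                         mode: str = "allele") -> pd.DataFrame:
    """Per-variant per-group alt frequency.

    ``allele`` mode: alt alleles / non-missing alleles; ``carrier`` mode:
    samples with dosage >= 1 / genotyped samples. NaN where a group has
    no calls at the variant.
    """
    if mode not in ("allele", "carrier"):
        raise ValueError("mode must be 'allele' or 'carrier'")
    dm = cohort.dosage_matrix()
    idx = groups.indices(cohort.sample_ids)
    out = {}
    for g, cols in sorted(idx.items()):
        sub = dm[:, cols]
        obs = sub != MISSING
        n = obs.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            if mode == "allele":
                freq = np.where(obs, sub, 0).sum(axis=1) / (2.0 * n)
            else:
                freq = (np.where(obs, sub, 0) >= 1).sum(axis=1) / n
        freq[n == 0] = np.nan
        out[g] = freq
    ids = [v.id or f"var{i + 1}" for i, v in enumerate(cohort.records)]
    return pd.DataFrame(out, index=ids)


def favored_svs(freqs: pd.DataFrame, focal: str,
                hi: float = 0.5, lo: float = 0.05,
                na_policy: str = "exclude") -> list[str]:
    """Variants favored in the focal group: frequency strictly > ``hi``
    there and strictly < ``lo`` in every other group.

    ``na_policy='exclude'`` (default, conservative) drops variants whose
    frequency is NaN in any non-focal group; ``'ignore'`` evaluates the
    rule over the non-NaN groups only.
    """
    if focal not in freqs.columns:
        raise KeyError(f"unknown group {focal!r}")
    if na_policy not in ("exclude", "ignore"):
        raise ValueError("na_policy must be 'exclude' or 'ignore'")
    others = [c for c in freqs.columns if c != focal]
    f_focal = freqs[focal]
    ok = f_focal > hi
    for g in others:
        fg = freqs[g]
        if na_policy == "exclude":
            ok &= fg < lo  # NaN comparison is False -> excluded
        else:
            ok &= fg.isna() | (fg < lo)
    return list(freqs.index[ok.fillna(False)])


# ---------------------------------------------------------------------------
# genes vs hotspot regions
# ---------------------------------------------------------------------------

HOTSPOT_CLASSES = ("SV-hotspot", "SV-hotspot-upstream", "non-SV-hotspot")


def classify_genes_by_hotspot(genes: GeneSet, hotspots: RegionSet,
                              upstream: int = 2000) -> pd.Series:
    """Gene classes against hotspot regions: body overlap wins, then the
    strand-aware 2-kb upstream window, else non-hotspot."""
    labels = {}
    for g in genes:
        if hotspots.overlaps(g.chrom, g.start, g.end):
            labels[g.id] = "SV-hotspot"
            continue
        up = g.upstream_window(upstream)
        if up and hotspots.overlaps(g.chrom, *up):
            labels[g.id] = "SV-hotspot-upstream"
        else:
            labels[g.id] = "non-SV-hotspot"
    return pd.Series(labels, name="hotspot_class")


def deg_fraction_by_class(classes: Mapping[str, str],
                          de_lists: Mapping[str, Iterable[str]],
                          fold_changes: Mapping[str, Mapping[str, float]] | None = None,
                          fold_threshold: float = 4.0) -> pd.DataFrame:
    """Percent differentially expressed genes per condition x gene class,
    optionally with the share showing > ``fold_threshold``-fold change."""
    by_class: dict[str, set[str]] = {}
    for gene, cls in classes.items():
        by_class.setdefault(cls, set()).add(gene)
    rows = []
    for cond, de in sorted(de_lists.items()):
        de_set = set(de)
        fc = (fold_changes or {}).get(cond, {})
        for cls in HOTSPOT_CLASSES:
            members = by_class.get(cls, set())
            if not members:
                rows.append({"condition": cond, "class": cls, "n_genes": 0,
                             "deg_pct": float("nan")})
                continue
            n_de = len(de_set & members)
            row = {
                "condition": cond,
                "class": cls,
                "n_genes": len(members),
                "deg_pct": round_half_up(100.0 * n_de / len(members)),
            }
            if fold_changes is not None:
                n_big = sum(
                    1 for g in de_set & members
                    if abs(fc.get(g, 0.0)) > fold_threshold
                )
                row["strong_deg_pct"] = round_half_up(100.0 * n_big / len(members))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotype-matrix filtering
# ---------------------------------------------------------------------------


def filter_sv_genotype_matrix(cohort: VariantCohort,
                              max_missing: float = 0.5,
                              maf: float = 0.05) -> VariantCohort:
    """Drop variants with missing-call rate > ``max_missing`` or minor
    allele frequency < ``maf`` (boundary kept, the PLINK convention)."""
    dm = cohort.dosage_matrix()
    obs = dm != MISSING
    n_samples = dm.shape[1] if dm.size else 0
    keep = []
    for i in range(dm.shape[0]):
        n_obs = int(obs[i].sum())
        miss_rate = 1.0 - n_obs / n_samples if n_samples else 1.0
        if miss_rate > max_missing:
            continue
        if n_obs == 0:
            continue
        af = float(dm[i][obs[i]].sum()) / (2.0 * n_obs)
        if min(af, 1.0 - af) < maf:
            continue
        keep.append(i)
    return cohort.subset(keep)
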