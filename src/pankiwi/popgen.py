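"""Population-genetic statistics: Weir-Cockerham FST, nucleotide
diversity, windowed scans, highly-differentiated-region calling and
distance-based variant thinning.

The FST estimator is the two-population diploid Weir & Cockerham (1984)
variance-component form: per site, ``a`` (among populations), ``b``
(among individuals within populations) and ``c`` (within individuals)
are computed from group allele frequencies and observed heterozygosities;
a window's weighted estimate is sum(a)/sum(a+b+c) over its usable sites,
the convention VCFtools reports as weighted FST. Samples missing at a
site drop out of that site's denominators only.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    GroupAssignment,
    RegionSet,
    Variant,
    VariantCohort,
    WindowTrack,
    tile_windows,
)

# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------


def _group_site_stats(dm: np.ndarray, idx: np.ndarray):
    """Per-site sample size, alt frequency and het fraction for one group."""
    sub = dm[:, idx]
    obs = sub != MISSING
    n = obs.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, sub, 0).sum(axis=1) / (2.0 * n)
        h = np.where(obs & (sub == 1), 1, 0).sum(axis=1) / n
    return n, p, h


def wc_components(dosage_matrix: np.ndarray,
                  idx1: np.ndarray,
                  idx2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site (a, b, c); NaN at sites that are unusable
    (< 2 genotyped diploids in either group, or monomorphic overall)."""
    n1, p1, h1 = _group_site_stats(dosage_matrix, idx1)
    n2, p2, h2 = _group_site_stats(dosage_matrix, idx2)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n1 + n2
        p_bar = (n1 * p1 + n2 * p2) / n_tot
        valid &= (p_bar > 0) & (p_bar < 1)
        h_bar = (n1 * h1 + n2 * h2) / n_tot
        n_bar = n_tot / 2.0
        n_c = n_tot - (n1**2 + n2**2) / n_tot
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        pq = p_bar * (1.0 - p_bar)
        a = (n_bar / n_c) * (
            s2 - (pq - s2 / 2.0 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            pq - s2 / 2.0 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def _pair_indices(cohort: VariantCohort, groups: GroupAssignment,
                  pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    idx = groups.indices(cohort.sample_ids)
    g1, g2 = pair
    for g in (g1, g2):
        if g not in idx:
            raise KeyError(f"group {g!r} has no samples in the cohort")
    if g1 == g2:
        raise ValueError("FST needs two distinct groups")
    return idx[g1], idx[g2]


def site_fst_wc(dosages: np.ndarray | Sequence[int],
                groups: GroupAssignment,
                sample_ids: Sequence[str],
                pair: tuple[str, str]) -> tuple[float, float, float, float]:
    """Single-site (a, b, c, fst); fst is NaN when a+b+c == 0 or the
    site is unusable."""
    dm = np.asarray(dosages, dtype=np.int16).reshape(1, -1)
    idx = groups.indices(sample_ids)
    a, b, c = wc_components(dm, idx[pair[0]], idx[pair[1]])
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    fst = a / denom if denom != 0 and not np.isnan(denom) else float("nan")
    return a, b, c, fst


def windowed_fst(cohort: VariantCohort,
                 groups: GroupAssignment,
                 pair: tuple[str, str],
                 window: int = 20_000,
                 step: int | None = None,
                 chrom_lengths: Mapping[str, int] | None = None) -> WindowTrack:
    """Weighted Weir-Cockerham FST in windows tiled from position 1.

    Default step equals the window size (non-overlapping 20-kb tiles).
    ``n_sites`` counts the usable (non-NaN component) sites per window.
    """
    if step is None:
        step = window
    idx1, idx2 = _pair_indices(cohort, groups, pair)
    dm = cohort.dosage_matrix()
    a, b, c = wc_components(dm, idx1, idx2)
    denom = a + b + c
    usable = ~np.isnan(denom) & (denom != 0)

    pos = np.array([v.pos for v in cohort.records])
    chrom = np.array([v.chrom for v in cohort.records])
    rows = []
    for ch in cohort.chroms():
        mask = chrom == ch
        length = (chrom_lengths or {}).get(ch, int(pos[mask].max()) if mask.any() else 1)
        p_ch = pos[mask]
        a_ch, d_ch, ok = a[mask], denom[mask], usable[mask]
        for ws, we in tile_windows(length, window, step):
            in_win = (p_ch >= ws) & (p_ch <= we) & ok
            n = int(in_win.sum())
            if n == 0:
                val = np.nan
            else:
                dsum = d_ch[in_win].sum()
                val = a_ch[in_win].sum() / dsum if dsum != 0 else np.nan
            rows.append((ch, ws, we, val, n))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_sites"])
    return WindowTrack(df, window, step)


def genome_wide_fst(cohort: VariantCohort,
                    groups: GroupAssignment,
                    pair: tuple[str, str]) -> float:
    """Single weighted estimate sum(a)/sum(a+b+c) over all usable sites."""
    idx1, idx2 = _pair_indices(cohort, groups, pair)
    a, b, c = wc_components(cohort.dosage_matrix(), idx1, idx2)
    denom = a + b + c
    ok = ~np.isnan(denom) & (denom != 0)
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


# ---------------------------------------------------------------------------
# percentile-threshold region calling (shared by HDRs and SV hotspots)
# ---------------------------------------------------------------------------


def call_percentile_regions(track: WindowTrack, percentile: float = 95.0) -> RegionSet:
    """Merge windows whose value strictly exceeds the stated percentile
    of all non-NA window values (linear interpolation between order
    statistics). Ties at the threshold are excluded, so a constant track
    yields no regions."""
    vals = track.values_valid()
    if vals.size == 0:
        return RegionSet([])
    threshold = float(np.percentile(vals, percentile))
    sel = track.windows[
        (~track.windows["value"].isna()) & (track.windows["value"] > threshold)
    ]
    if sel.empty:
        return RegionSet([])
    return RegionSet.merge(
        (r.chrom, int(r.start), int(r.end)) for r in sel.itertuples()
    )


def call_hdr(track: WindowTrack, percentile: float = 95.0) -> RegionSet:
    """Highly differentiated regions: windows above the FST percentile
    threshold, merged."""
    return call_percentile_regions(track, percentile)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def site_pi(dosages: np.ndarray | Sequence[int]) -> float:
    """Per-site nucleotide diversity 2 j (n - j) / (n (n - 1)) with j the
    alt-allele count and n the number of non-missing alleles."""
    d = np.asarray(dosages, dtype=np.int16)
    obs = d != MISSING
    n = 2 * int(obs.sum())
    if n < 2:
        return float("nan")
    j = int(d[obs].sum())
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def mean_pi(cohort: VariantCohort, sites: Sequence[int] | None = None) -> float:
    """Mean of site pi over the given record indices (default: all)."""
    records = cohort.records if sites is None else [cohort.records[i] for i in sites]
    vals = [site_pi(v.dosages) for v in records]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------


def thin_variants(cohort: VariantCohort, min_gap: int = 2000) -> VariantCohort:
    """Greedy left-to-right distance filter per chromosome: keep a site
    iff it lies at least ``min_gap`` bp beyond the last kept site."""
    keep: list[int] = []
    last: dict[str, int] = {}
    for i, v in enumerate(cohort.records):
        if v.chrom not in last or v.pos >= last[v.chrom] + min_gap:
            keep.append(i)
            last[v.chrom] = v.pos
    return cohort.subset(keep)
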