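"""Core in-memory containers shared by every analysis stage.

Coordinates are 1-based inclusive throughout (GFF/VCF native); the
0-based half-open BED convention appears only at the I/O boundary.
Missing diploid dosages are encoded as -1 in integer arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SV_TYPES = ("INS", "DEL", "INV")
VARIANT_TYPES = ("SNP",) + SV_TYPES
RGA_CLASSES = ("NBS", "RLK", "RLP", "TM-CC")

#: minimum span for a variant to qualify as a structural variant
SV_MIN_LENGTH = 50


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention used in all
    percentage reports (so 0.675 -> 0.68, not banker's 0.67)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# gene-family occupancy matrix
# ---------------------------------------------------------------------------


@dataclass
class FamilyMatrix:
    """Dense gene-family x assembly count table.

    ``counts`` holds the number of member genes of each family in each
    assembly (explicit zeros). ``gene_members`` optionally maps
    ``(family_id, assembly_id)`` to the member gene identifiers.
    """

    counts: pd.DataFrame
    gene_members: dict[tuple[str, str], list[str]] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate family IDs: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate assembly IDs")
        if (self.counts.values < 0).any():
            raise ValueError("negative gene counts")
        totals = self.counts.sum(axis=1)
        if (totals < 1).any():
            empty = totals.index[totals < 1].tolist()
            raise ValueError(f"families with no genes anywhere: {empty[:5]}")

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def assembly_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_assemblies(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> pd.Series:
        """Number of assemblies in which each family has >= 1 gene."""
        return (self.counts >= 1).sum(axis=1)

    def gene_totals(self) -> pd.Series:
        """Total member genes of each family across all assemblies."""
        return self.counts.sum(axis=1)

    def restrict(self, families: Iterable[str]) -> "FamilyMatrix":
        keep = [f for f in families]
        missing = set(keep) - set(self.counts.index)
        if missing:
            raise KeyError(f"unknown families: {sorted(missing)[:5]}")
        members = None
        if self.gene_members is not None:
            keep_set = set(keep)
            members = {k: v for k, v in self.gene_members.items() if k[0] in keep_set}
        return FamilyMatrix(self.counts.loc[keep].copy(), members)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


@dataclass
class Variant:
    """One biallelic variant with per-sample alt-dosages (0/1/2, -1 missing)."""

    chrom: str
    pos: int
    vtype: str
    length: int
    dosages: np.ndarray
    id: str | None = None

    def __post_init__(self) -> None:
        if self.vtype not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.length < 1:
            raise ValueError(f"variant length must be >= 1, got {self.length}")
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage values {np.unique(self.dosages[bad])}")

    @property
    def is_sv(self) -> bool:
        return self.vtype in SV_TYPES

    def span(self) -> tuple[int, int]:
        """Genomic footprint: insertions occupy their single anchor base,
        deletions/inversions their full extent."""
        if self.vtype == "INS":
            return self.pos, self.pos
        return self.pos, self.pos + self.length - 1


@dataclass
class VariantCohort:
    """Position-sorted variants genotyped over one fixed sample panel."""

    records: list[Variant]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        n = len(self.sample_ids)
        last: dict[str, int] = {}
        for v in self.records:
            if len(v.dosages) != n:
                raise ValueError(
                    f"variant {v.id or v.pos} has {len(v.dosages)} dosages for {n} samples"
                )
            if v.chrom in last and v.pos < last[v.chrom]:
                raise ValueError(f"records not sorted at {v.chrom}:{v.pos}")
            last[v.chrom] = v.pos

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dosage_matrix(self) -> np.ndarray:
        """(n_variants, n_samples) int16 matrix, -1 = missing."""
        if not self.records:
            return np.empty((0, len(self.sample_ids)), dtype=np.int16)
        return np.vstack([v.dosages for v in self.records])

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.records:
            seen.setdefault(v.chrom, None)
        return list(seen)

    def subset(self, keep: Sequence[int]) -> "VariantCohort":
        return VariantCohort([self.records[i] for i in keep], list(self.sample_ids))


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    family_id: str | None = None
    rga_class: str | None = None
    exons: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.rga_class is not None and self.rga_class not in RGA_CLASSES:
            raise ValueError(f"gene {self.id}: unknown RGA class {self.rga_class!r}")

    def upstream_window(self, flank: int) -> tuple[int, int] | None:
        """Strand-aware flank 5' of the gene, clipped at position 1."""
        if self.strand == "+":
            lo, hi = self.start - flank, self.start - 1
        elif self.strand == "-":
            lo, hi = self.end + 1, self.end + flank
        else:
            return None
        lo = max(lo, 1)
        return (lo, hi) if lo <= hi else None

    def downstream_window(self, flank: int) -> tuple[int, int] | None:
        if self.strand == "+":
            lo, hi = self.end + 1, self.end + flank
        elif self.strand == "-":
            lo, hi = self.start - flank, self.start - 1
        else:
            return None
        lo = max(lo, 1)
        return (lo, hi) if lo <= hi else None


@dataclass
class GeneSet:
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene IDs")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.end, g.id))
        return out

    def of_class(self, rga_class: str) -> list[Gene]:
        return [g for g in self.genes if g.rga_class == rga_class]

    def has_exons(self) -> bool:
        return any(g.exons for g in self.genes)


# ---------------------------------------------------------------------------
# sample groups
# ---------------------------------------------------------------------------


@dataclass
class GroupAssignment:
    """sample -> group label map (e.g. LG / MG1 / MG2)."""

    mapping: dict[str, str]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.mapping.items():
            out.setdefault(g, []).append(s)
        return out

    def group_of(self, sample: str) -> str:
        return self.mapping[sample]

    def indices(self, sample_ids: Sequence[str]) -> dict[str, np.ndarray]:
        """Column indices of each group within an ordered sample panel;
        every panel sample must be assigned exactly once."""
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise KeyError(f"samples without a group: {missing[:5]}")
        out: dict[str, list[int]] = {}
        for i, s in enumerate(sample_ids):
            out.setdefault(self.mapping[s], []).append(i)
        return {g: np.asarray(ix, dtype=np.intp) for g, ix in out.items()}

    def merged(self, union: Mapping[str, Sequence[str]]) -> "GroupAssignment":
        """Relabel groups, pooling e.g. {'MG': ['MG1', 'MG2']}."""
        rename = {old: new for new, olds in union.items() for old in olds}
        return GroupAssignment(
            {s: rename.get(g, g) for s, g in self.mapping.items()}
        )


# ---------------------------------------------------------------------------
# genomic regions and window tracks
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """Sorted, pairwise-disjoint 1-based inclusive intervals."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        order: dict[str, None] = {}
        for chrom, start, end in self.intervals:
            if start > end or start < 1:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            if chrom in prev and start <= prev[chrom]:
                raise ValueError(f"intervals overlap or unsorted at {chrom}:{start}")
            prev[chrom] = end
            order.setdefault(chrom, None)

    @classmethod
    def merge(cls, intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        """Union of intervals: overlapping or bookended (adjacent) pieces
        are fused into one region."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            spans = sorted(by_chrom[chrom])
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        return cls(merged)

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(
            c == chrom and s <= end and start <= e for c, s, e in self.intervals
        )


@dataclass
class WindowTrack:
    """Per-window statistic values; ``value`` is NaN where n_sites == 0."""

    windows: pd.DataFrame  # columns: chrom, start, end, value, n_sites
    window_size: int
    step: int

    REQUIRED = ("chrom", "start", "end", "value", "n_sites")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.windows.columns:
                raise ValueError(f"window table lacks column {col!r}")
        if (self.windows["n_sites"] < 0).any():
            raise ValueError("negative n_sites")

    def values_valid(self) -> np.ndarray:
        v = self.windows["value"].to_numpy(dtype=float)
        return v[~np.isnan(v)]

    def __len__(self) -> int:
        return len(self.windows)


def tile_windows(chrom_length: int, size: int, step: int) -> list[tuple[int, int]]:
    """Windows anchored at position 1: starts 1, 1+step, ... while the
    start lies on the chromosome; ends clipped to the chromosome."""
    if size < 1 or step < 1:
        raise ValueError("window size and step must be >= 1")
    out = []
    start = 1
    while start <= chrom_length:
        out.append((start, min(start + size - 1, chrom_length)))
        start += step
    return out


# ---------------------------------------------------------------------------
# pan-genome partition
# ---------------------------------------------------------------------------


@dataclass
class PartitionThresholds:
    """Occupancy bands over N assemblies.

    core: present in all N; softcore: softcore_min..N-1 (default
    ceil(0.85 N)); dispensable: 2..softcore_min-1; cloud: exactly 1.
    """

    n_assemblies: int
    softcore_min: int | None = None

    def __post_init__(self) -> None:
        if self.softcore_min is None:
            self.softcore_min = ceil(0.85 * self.n_assemblies)
        if self.softcore_min <= 2:
            raise ValueError(
                f"softcore_min={self.softcore_min} collides with the dispensable "
                f"band; use more assemblies (N={self.n_assemblies})"
            )
        if self.softcore_min > self.n_assemblies:
            raise ValueError("softcore_min exceeds assembly count")

    def category_of(self, frequency: int) -> str:
        n = self.n_assemblies
        if not 1 <= frequency <= n:
            raise ValueError(f"frequency {frequency} outside 1..{n}")
        if frequency == n:
            return "core"
        if frequency >= self.softcore_min:
            return "softcore"
        if frequency >= 2:
            return "dispensable"
        return "cloud"

    def band(self, category: str) -> tuple[int, int]:
        n = self.n_assemblies
        return {
            "core": (n, n),
            "softcore": (self.softcore_min, n - 1),
            "dispensable": (2, self.softcore_min - 1),
            "cloud": (1, 1),
        }[category]


CATEGORIES = ("core", "softcore", "dispensable", "cloud")


@dataclass
class PartitionResult:
    categories: pd.Series  # family -> category
    family_counts: dict[str, int]
    gene_counts: dict[str, int]
    per_assembly: pd.DataFrame | None = None  # assembly x category gene counts

    def __post_init__(self) -> None:
        n_fam = len(self.categories)
        if n_fam and sum(self.family_counts.values()) != n_fam:
            raise ValueError("category family counts do not sum to total families")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    n_sites: np.ndarray | None = None  # co-genotyped site count per pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.sample_ids)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.values[i, j])
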