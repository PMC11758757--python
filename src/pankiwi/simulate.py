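"""Synthetic inputs with the statistical structure the analyses assume,
plus ground-truth labels, so every downstream stage is testable without
external genomes.

The generators emulate a 15-assembly gene-family matrix with tunable
occupancy-category proportions, SNP cohorts under the Balding-Nichols
differentiation model (Beta-distributed group allele frequencies with a
known expected FST), SV cohorts with planted group-favored variants, and
GFF gene sets containing physical RGA clusters and divergent paired
NLRs. Everything is driven by one numpy Generator: a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    FamilyMatrix,
    Gene,
    GeneSet,
    GroupAssignment,
    PartitionThresholds,
    Variant,
    VariantCohort,
)


@dataclass
class SimulationConfig:
    """All knobs for the synthetic generators, with defaults mirroring
    the 15-assembly / three-group study design the package targets.

    ``category_targets`` are family counts per occupancy category in the
    proportions observed for large plant pan-genomes (roughly 24% core,
    9% softcore, 35% dispensable, 33% cloud). ``fst_target`` is the
    Balding-Nichols F; 0.2 is a typical between-subgenus differentiation
    level. SV lengths default to log-uniform 50 bp - 10 kb.
    """

    seed: int = 0
    # family matrix
    n_assemblies: int = 15
    category_targets: dict = field(
        default_factory=lambda: {
            "core": 236, "softcore": 87, "dispensable": 347, "cloud": 330
        }
    )
    # genotype cohorts
    groups: dict = field(
        default_factory=lambda: {"LG": 20, "MG1": 20, "MG2": 20}
    )
    fst_target: float = 0.2
    n_sites: int = 10_000
    chromosome_lengths: dict = field(
        default_factory=lambda: {"Chr01": 10_000_000, "Chr02": 10_000_000}
    )
    missing_rate: float = 0.0
    # SV cohort
    n_svs: int = 2000
    sv_favored_fraction: dict = field(default_factory=lambda: {"LG": 0.1})
    sv_background_freq: tuple = (0.2, 0.8)
    sv_favored_focal_freq: tuple = (0.6, 1.0)
    sv_favored_other_freq: tuple = (0.0, 0.03)
    sv_length_range: tuple = (50, 10_000)
    sv_type_weights: dict = field(
        default_factory=lambda: {"INS": 0.45, "DEL": 0.45, "INV": 0.10}
    )
    exact_frequencies: bool = False
    # RGA gene layout
    rga_chrom: str = "Chr01"
    n_clusters: int = 5
    cluster_size_range: tuple = (2, 5)
    n_paired_nlr: int = 4
    n_decoy_pairs: int = 2
    n_singletons: int = 10
    cluster_max_gap: int = 200_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        if any(v < 0 for v in self.category_targets.values()):
            raise ValueError("negative category target")
        if any(v < 0 for v in self.groups.values()):
            raise ValueError("negative group size")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sample_panel(self) -> tuple[list[str], GroupAssignment]:
        samples, mapping = [], {}
        for g in self.groups:
            for i in range(self.groups[g]):
                s = f"{g}_{i + 1:02d}"
                samples.append(s)
                mapping[s] = g
        return samples, GroupAssignment(mapping)


# ---------------------------------------------------------------------------
# family matrix
# ---------------------------------------------------------------------------


def assembly_panel(n_assemblies: int = 15) -> tuple[list[str], dict[str, str]]:
    """Assembly names and their group labels: 4 LG, 4 MG1 and the rest
    MG2, echoing the 15-assembly split of the target study design."""
    names = [f"asm{i + 1:02d}" for i in range(n_assemblies)]
    groups = {}
    for i, name in enumerate(names):
        groups[name] = "LG" if i < 4 else ("MG1" if i < 8 else "MG2")
    return names, groups


def simulate_family_matrix(cfg: SimulationConfig) -> tuple[FamilyMatrix, dict[str, str]]:
    """Family matrix with planted occupancy categories.

    Each family's assembly frequency is drawn uniformly from its
    category's band (core: N; softcore: ceil(0.85 N)..N-1; dispensable:
    2..ceil(0.85 N)-1; cloud: 1); occupied cells carry >= 1 gene with a
    light Poisson tail for paralogs. Returns the matrix and the planted
    family -> category truth.
    """
    n = cfg.n_assemblies
    thr = PartitionThresholds(n)  # raises if the bands collide
    bands = {c: thr.band(c) for c in ("core", "softcore", "dispensable", "cloud")}
    rng = cfg.rng()
    assemblies, _ = assembly_panel(n)

    fam_ids, rows, truth = [], [], {}
    members: dict[tuple[str, str], list[str]] = {}
    fam_no = 0
    for cat in ("core", "softcore", "dispensable", "cloud"):
        lo, hi = bands[cat]
        for _ in range(int(cfg.category_targets.get(cat, 0))):
            fam_no += 1
            fam = f"OG{fam_no:05d}"
            freq = int(rng.integers(lo, hi + 1))
            present = rng.choice(n, size=freq, replace=False)
            row = np.zeros(n, dtype=int)
            row[present] = 1 + rng.poisson(0.3, size=freq)
            for ai in present:
                asm = assemblies[ai]
                members[(fam, asm)] = [
                    f"{asm}.{fam}.g{k + 1}" for k in range(row[ai])
                ]
            fam_ids.append(fam)
            rows.append(row)
            truth[fam] = cat
    counts = pd.DataFrame(rows, index=fam_ids, columns=assemblies)
    return FamilyMatrix(counts, members), truth


# ---------------------------------------------------------------------------
# genotype cohorts
# ---------------------------------------------------------------------------


def _positions(rng: np.random.Generator, chrom_lengths: dict, n_sites: int
               ) -> list[tuple[str, int]]:
    """n_sites unique positions spread over chromosomes proportionally
    to length, sorted within each chromosome."""
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    alloc = {c: int(round(n_sites * chrom_lengths[c] / total)) for c in chroms}
    drift = n_sites - sum(alloc.values())
    alloc[chroms[0]] += drift
    out = []
    for c in chroms:
        want = alloc[c]
        length = chrom_lengths[c]
        if want > length:
            raise ValueError(f"{c}: more sites requested than positions available")
        pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(want * 1.2) + 8))
        while pos.size < want:
            extra = rng.integers(1, length + 1, size=want)
            pos = np.unique(np.concatenate([pos, extra]))
        chosen = np.sort(rng.choice(pos, size=want, replace=False))
        out.extend((c, int(p)) for p in chosen)
    return out


def _apply_missing(rng: np.random.Generator, dosages: np.ndarray,
                   rate: float) -> np.ndarray:
    if rate > 0:
        mask = rng.random(dosages.shape) < rate
        dosages = np.where(mask, MISSING, dosages)
    return dosages.astype(np.int16)


def simulate_snp_cohort(cfg: SimulationConfig) -> VariantCohort:
    """Balding-Nichols SNP cohort with expected FST = ``fst_target``.

    Per site: ancestral frequency p ~ Uniform(0.05, 0.95); each group's
    frequency ~ Beta(p (1-F)/F, (1-p) (1-F)/F) (F = 0 degenerates to p
    itself); diploid dosages ~ Binomial(2, group frequency).
    """
    if len(cfg.groups) < 2 or any(v < 2 for v in cfg.groups.values()):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    rng = cfg.rng()
    samples, assignment = cfg.sample_panel()
    sites = _positions(rng, cfg.chromosome_lengths, cfg.n_sites)
    F = cfg.fst_target
    group_sizes = [cfg.groups[g] for g in cfg.groups]

    records = []
    for i, (chrom, pos) in enumerate(sites):
        p = rng.uniform(0.05, 0.95)
        dos_parts = []
        for n_g in group_sizes:
            if F == 0.0:
                pg = p
            else:
                pg = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
            dos_parts.append(rng.binomial(2, pg, size=n_g))
        dosages = _apply_missing(rng, np.concatenate(dos_parts), cfg.missing_rate)
        records.append(Variant(chrom, pos, "SNP", 1, dosages, f"snp{i + 1:06d}"))
    return VariantCohort(records, samples)


def _exact_dosages(n_samples: int, freq: float) -> np.ndarray:
    """Deterministic dosage vector realizing ``freq`` as closely as a
    2n-allele pool allows (used by the exact-frequency mode)."""
    alt = int(round(2 * n_samples * freq))
    full, het = divmod(alt, 2)
    return np.array([2] * full + [1] * het + [0] * (n_samples - full - het),
                    dtype=np.int16)


def simulate_sv_cohort(cfg: SimulationConfig) -> tuple[VariantCohort, dict[str, str | None]]:
    """SV cohort with planted group-favored variants.

    For each focal group in ``sv_favored_fraction``, that fraction of
    SVs gets a focal-group allele frequency ~ Uniform(0.6, 1.0) and
    near-zero frequencies (Uniform(0, 0.03)) everywhere else; the
    remaining SVs share one background frequency ~ Uniform(0.2, 0.8)
    across all groups. Genotypes are binomial draws from the group
    frequency (or deterministic in ``exact_frequencies`` mode). Lengths
    are log-uniform over ``sv_length_range`` (all >= 50 bp); types are
    drawn from ``sv_type_weights``.

    Returns the cohort and the truth map sv_id -> favored group (None
    for background SVs).
    """
    rng = cfg.rng()
    samples, assignment = cfg.sample_panel()
    group_names = list(cfg.groups)
    sites = _positions(rng, cfg.chromosome_lengths, cfg.n_svs)

    n_svs = cfg.n_svs
    labels: list[str | None] = [None] * n_svs
    remaining = list(range(n_svs))
    for focal, frac in cfg.sv_favored_fraction.items():
        if focal not in cfg.groups:
            raise KeyError(f"favored group {focal!r} not in groups")
        k = int(round(frac * n_svs))
        chosen = rng.choice(len(remaining), size=k, replace=False)
        chosen_idx = [remaining[i] for i in sorted(chosen)]
        for i in chosen_idx:
            labels[i] = focal
        remaining = [i for i in remaining if labels[i] is None]

    types = list(cfg.sv_type_weights)
    weights = np.array([cfg.sv_type_weights[t] for t in types], dtype=float)
    weights /= weights.sum()
    lo, hi = cfg.sv_length_range
    if lo < 50:
        raise ValueError("SV lengths must be >= 50 bp")

    truth: dict[str, str | None] = {}
    records = []
    for i, (chrom, pos) in enumerate(sites):
        vid = f"sv{i + 1:06d}"
        focal = labels[i]
        if focal is None:
            f_shared = rng.uniform(*cfg.sv_background_freq)
            group_freqs = {g: f_shared for g in group_names}
        else:
            group_freqs = {
                g: (rng.uniform(*cfg.sv_favored_focal_freq) if g == focal
                    else rng.uniform(*cfg.sv_favored_other_freq))
                for g in group_names
            }
        parts = []
        for g in group_names:
            n_g = cfg.groups[g]
            if cfg.exact_frequencies:
                parts.append(_exact_dosages(n_g, group_freqs[g]))
            else:
                parts.append(rng.binomial(2, group_freqs[g], size=n_g))
        dosages = _apply_missing(rng, np.concatenate(parts), cfg.missing_rate)
        vtype = types[int(rng.choice(len(types), p=weights))]
        length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        records.append(Variant(chrom, pos, vtype, max(length, 50), dosages, vid))
        truth[vid] = focal
    return VariantCohort(records, samples), truth


# ---------------------------------------------------------------------------
# RGA gene sets
# ---------------------------------------------------------------------------


def simulate_rga_geneset(cfg: SimulationConfig) -> tuple[GeneSet, dict]:
    """Gene set with planted RGA clusters and paired NLRs.

    Cluster blocks are same-family NBS genes with intra-cluster gaps
    < 200 kb; blocks (and everything else) are separated by > 200 kb so
    each planted cluster is recoverable as exactly one called cluster.
    Paired NLRs are adjacent NBS genes with strands (-,+) in coordinate
    order and a small gap; decoy pairs are tail-to-tail (+,-) and must
    not be called. Singleton filler genes carry unique families and
    random non-pairing orientations.

    Truth: ``{"clusters": [[gene ids]], "pairs": [(left, right)],
    "decoys": [(left, right)]}``.
    """
    rng = cfg.rng()
    chrom = cfg.rga_chrom
    genes: list[Gene] = []
    truth: dict = {"clusters": [], "pairs": [], "decoys": []}
    cursor = int(rng.integers(50_000, 150_000))
    gid = 0
    fam_no = 0

    def next_block_gap() -> int:
        # strictly beyond the clustering reach
        return int(rng.integers(cfg.cluster_max_gap + 50_000, cfg.cluster_max_gap + 300_000))

    def add_gene(start: int, length: int, strand: str, family: str,
                 rga_class: str | None) -> Gene:
        nonlocal gid
        gid += 1
        end = start + length - 1
        # simple exon model: 1-3 exons separated by short introns
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(start + 1, end), 2 * (n_exons - 1),
                                  replace=False)) if n_exons > 1 else np.array([])
        bounds = [start, *cuts.tolist(), end]
        exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1]))
                 for k in range(n_exons)]
        g = Gene(f"g{gid:04d}", chrom, start, end, strand,
                 family_id=family, rga_class=rga_class, exons=exons)
        genes.append(g)
        return g

    for _ in range(cfg.n_clusters):
        fam_no += 1
        fam = f"RGAfam{fam_no:03d}"
        size = int(rng.integers(cfg.cluster_size_range[0], cfg.cluster_size_range[1] + 1))
        ids = []
        for k in range(size):
            length = int(rng.integers(2_000, 6_000))
            g = add_gene(cursor, length, "+", fam, "NBS")
            ids.append(g.id)
            intra = int(rng.integers(5_000, cfg.cluster_max_gap - 50_000))
            cursor = g.end + 1 + intra
        truth["clusters"].append(ids)
        cursor += next_block_gap()

    for _ in range(cfg.n_paired_nlr):
        fam_no += 1
        left = add_gene(cursor, int(rng.integers(2_000, 6_000)), "-",
                        f"PairFamL{fam_no:03d}", "NBS")
        gap = int(rng.integers(1_000, 10_000))
        fam_no += 1
        right = add_gene(left.end + 1 + gap, int(rng.integers(2_000, 6_000)), "+",
                         f"PairFamR{fam_no:03d}", "NBS")
        truth["pairs"].append((left.id, right.id))
        cursor = right.end + 1 + next_block_gap()

    for _ in range(cfg.n_decoy_pairs):
        fam_no += 1
        left = add_gene(cursor, int(rng.integers(2_000, 6_000)), "+",
                        f"DecoyFamL{fam_no:03d}", "NBS")
        gap = int(rng.integers(1_000, 10_000))
        fam_no += 1
        right = add_gene(left.end + 1 + gap, int(rng.integers(2_000, 6_000)), "-",
                         f"DecoyFamR{fam_no:03d}", "NBS")
        truth["decoys"].append((left.id, right.id))
        cursor = right.end + 1 + next_block_gap()

    classes = ["RLK", "RLP", "TM-CC", "NBS"]
    for _ in range(cfg.n_singletons):
        fam_no += 1
        cls = classes[int(rng.integers(0, len(classes)))]
        strand = "+" if cls == "NBS" else ("+" if rng.random() < 0.5 else "-")
        g = add_gene(cursor, int(rng.integers(2_000, 6_000)), strand,
                     f"SingleFam{fam_no:03d}", cls)
        cursor = g.end + 1 + next_block_gap()

    return GeneSet(genes), truth
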