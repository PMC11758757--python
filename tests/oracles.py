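"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain loops over definitions, deliberately
sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import random


# --- Weir & Cockerham (1984), two populations, diploid, per site --------


def wc_fst_site(geno1: list[int], geno2: list[int]) -> tuple[float, float, float, float]:
    """Direct transcription of the variance-component formulas from the
    published two-population estimator; -1 = missing genotype."""
    g1 = [g for g in geno1 if g >= 0]
    g2 = [g for g in geno2 if g >= 0]
    n1, n2 = len(g1), len(g2)
    nan = float("nan")
    if n1 < 2 or n2 < 2:
        return nan, nan, nan, nan
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    r = 2
    n_bar = (n1 + n2) / r
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    if p_bar <= 0 or p_bar >= 1:
        return nan, nan, nan, nan
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    return a, b, c, (a / denom if denom != 0 else nan)


# --- nucleotide diversity by pairwise allele mismatch counting ----------


def pi_site(genotypes: list[int]) -> float:
    """Mean mismatch over all unordered allele pairs at the site."""
    alleles: list[int] = []
    for g in genotypes:
        if g < 0:
            continue
        alleles.extend([1] * g + [0] * (2 - g))
    n = len(alleles)
    if n < 2:
        return float("nan")
    mismatches = sum(
        1 for a, b in itertools.combinations(alleles, 2) if a != b
    )
    return mismatches / (n * (n - 1) / 2)


# --- genic context by exhaustive (variant, feature) checks --------------


def sv_context(span: tuple[int, int], chrom: str, genes: list[dict],
               flank: int = 1000) -> str:
    """genes: dicts with chrom/start/end/strand/exons. Checks every
    feature of every gene and applies the precedence ladder."""
    s, e = span

    def hits(lo, hi):
        return s <= hi and lo <= e

    found = set()
    for g in genes:
        if g["chrom"] != chrom:
            continue
        if hits(g["start"], g["end"]):
            if any(hits(xs, xe) for xs, xe in g.get("exons") or []):
                found.add("exon")
            else:
                found.add("intron")
            continue
        if g["strand"] == "+":
            up = (g["start"] - flank, g["start"] - 1)
            down = (g["end"] + 1, g["end"] + flank)
        else:
            up = (g["end"] + 1, g["end"] + flank)
            down = (g["start"] - flank, g["start"] - 1)
        if up[0] <= up[1] and hits(max(up[0], 1), up[1]):
            found.add("upstream")
        if down[0] <= down[1] and hits(max(down[0], 1), down[1]):
            found.add("downstream")
    for cat in ("exon", "intron", "upstream", "downstream"):
        if cat in found:
            return cat
    return "intergenic"


# --- favored-SV rule, literal evaluation --------------------------------


def favored(freq_by_group: dict[str, float], focal: str,
            hi: float = 0.5, lo: float = 0.05) -> bool:
    import math

    f = freq_by_group[focal]
    if math.isnan(f) or not f > hi:
        return False
    for g, fg in freq_by_group.items():
        if g == focal:
            continue
        if math.isnan(fg) or not fg < lo:
            return False
    return True


# --- PLINK-style per-record filter --------------------------------------


def passes_filters(dosages: list[int], max_missing: float = 0.5,
                   maf: float = 0.05) -> bool:
    n = len(dosages)
    obs = [d for d in dosages if d >= 0]
    if n == 0 or (n - len(obs)) / n > max_missing:
        return False
    if not obs:
        return False
    af = sum(obs) / (2 * len(obs))
    return min(af, 1 - af) >= maf


# --- single-linkage clustering via union-find over all pairs ------------


def cluster_union_find(genes: list[dict], max_gap: int = 200_000) -> list[list[str]]:
    """All-pairs union-find: two same-family, same-chromosome genes
    connect when the gap between their spans is <= max_gap. Equivalent
    to successive-gene chaining for non-nested gene layouts."""
    parent = {g["id"]: g["id"] for g in genes if g.get("family") is not None}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    eligible = [g for g in genes if g.get("family") is not None]
    for g1, g2 in itertools.combinations(eligible, 2):
        if g1["chrom"] != g2["chrom"] or g1["family"] != g2["family"]:
            continue
        gap = max(
            max(g1["start"], g2["start"]) - min(g1["end"], g2["end"]) - 1, 0
        )
        if gap <= max_gap:
            union(g1["id"], g2["id"])
    groups: dict[str, list[str]] = {}
    for g in eligible:
        groups.setdefault(find(g["id"]), []).append(g["id"])
    return sorted(
        sorted(v) for v in groups.values() if len(v) >= 2
    )


# --- random additive trees for NJ consistency checks --------------------


def random_additive_tree(rng: random.Random, n_taxa: int
                         ) -> tuple[str, dict[tuple[str, str], float]]:
    """A random unrooted binary tree with positive branch lengths.
    Returns its Newick string and the exact leaf-to-leaf path lengths
    (an additive distance matrix)."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    dists: dict[tuple[str, str], float] = {}

    def record_cross(d_i: dict, d_j: dict) -> None:
        for a in d_i:
            for b in d_j:
                dists[tuple(sorted((a, b)))] = d_i[a] + d_j[b]

    # each cluster: (newick, {leaf: dist to cluster root})
    clusters = [(lab, {lab: 0.0}) for lab in labels]
    while len(clusters) > 3:
        i, j = rng.sample(range(len(clusters)), 2)
        i, j = min(i, j), max(i, j)
        (nwk_j, d_j) = clusters.pop(j)
        (nwk_i, d_i) = clusters.pop(i)
        bi = rng.uniform(0.05, 1.0)
        bj = rng.uniform(0.05, 1.0)
        d_i = {k: v + bi for k, v in d_i.items()}
        d_j = {k: v + bj for k, v in d_j.items()}
        record_cross(d_i, d_j)
        clusters.append((f"({nwk_i}:{bi:.6f},{nwk_j}:{bj:.6f})", {**d_i, **d_j}))
    parts, depth_maps = [], []
    for nwk, dmap in clusters:
        b = rng.uniform(0.05, 1.0)
        parts.append(f"{nwk}:{b:.6f}")
        depth_maps.append({k: v + b for k, v in dmap.items()})
    newick = "(" + ",".join(parts) + ");"
    for mi, mj in itertools.combinations(depth_maps, 2):
        record_cross(mi, mj)
    return newick, dists
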