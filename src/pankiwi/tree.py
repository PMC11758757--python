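"""p-distance matrices from genotype cohorts and neighbor-joining trees.

The pairwise distance is the mean per-site dosage difference
|d_i - d_j| / 2 over sites where both samples are genotyped — the
proportion of allele differences between two diploids, matching the
p-distance contract of VCF2Dis-style tools. Trees are built with plain
Saitou-Nei neighbor joining (Studier-Keppler Q criterion), which is
consistent on additive matrices; ties in Q are broken by lexicographic
taxon-pair order and negative branch lengths are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .model import MISSING, DistanceMatrix, VariantCohort


def p_distance_matrix(cohort: VariantCohort, mode: str = "dosage") -> DistanceMatrix:
    """Pairwise p-distances over co-genotyped sites.

    ``dosage`` mode: site distance |d_i - d_j| / 2 — identical to
    counting shared alleles, since two diploids share 2 - |d_i - d_j|
    alleles at a biallelic site. ``expected-mismatch`` mode instead
    takes the chance that one allele drawn from each sample differs
    (f_i + f_j - 2 f_i f_j with f = dosage/2), which scores a het-het
    comparison 0.5 rather than 0. A pair with zero co-genotyped sites
    is an error.
    """
    if mode not in ("dosage", "expected-mismatch"):
        raise ValueError("mode must be 'dosage' or 'expected-mismatch'")
    if cohort.n_samples < 2:
        raise ValueError("need >= 2 samples")
    dm = cohort.dosage_matrix().astype(float)
    dm[dm == MISSING] = np.nan
    k = cohort.n_samples
    values = np.zeros((k, k))
    n_sites = np.zeros((k, k), dtype=np.int64)
    for i, j in combinations(range(k), 2):
        both = ~np.isnan(dm[:, i]) & ~np.isnan(dm[:, j])
        n = int(both.sum())
        if n == 0:
            raise ValueError(
                f"samples {cohort.sample_ids[i]!r} and {cohort.sample_ids[j]!r} "
                "share no genotyped sites"
            )
        di, dj = dm[both, i], dm[both, j]
        if mode == "dosage":
            d = float(np.abs(di - dj).mean() / 2.0)
        else:
            fi, fj = di / 2.0, dj / 2.0
            d = float((fi + fj - 2.0 * fi * fj).mean())
        values[i, j] = values[j, i] = d
        n_sites[i, j] = n_sites[j, i] = n
    return DistanceMatrix(list(cohort.sample_ids), values, n_sites)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Minimal rooted representation of an unrooted tree: the root of a
    neighbor-joining result is the final 3-way (or 2-way) join."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


def to_newick(node: TreeNode, digits: int = 6) -> str:
    def render(n: TreeNode) -> str:
        if n.is_leaf:
            return n.name or ""
        inner = ",".join(
            f"{render(child)}:{length:.{digits}f}" for child, length in n.children
        )
        return f"({inner})"

    return render(node) + ";"


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining on a symmetric distance matrix (>= 3 taxa).

    Deterministic: among Q-minimal pairs the lexicographically smallest
    (sorted) pair of subtree labels is joined; a subtree's label is the
    smallest leaf name it contains. Negative branch lengths are clamped
    to zero (their deficit is recorded on the node order, not the tree).
    """
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.sample_ids]
    labels: list[str] = list(dm.sample_ids)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai, aj in combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
            key = (q, tuple(sorted((labels[active[ai]], labels[active[aj]]))))
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # closing 3-way join: three-point formulas
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = (dij + dik - djk) / 2.0
    lj = (dij + djk - dik) / 2.0
    lk = (dik + djk - dij) / 2.0
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return root


def tree_path_lengths(root: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (sorted name pairs) — the additivity
    check used to validate NJ consistency."""
    # distance of every leaf from the root by accumulation
    dist_to_root: dict[str, float] = {}
    parent_paths: dict[str, list[tuple[TreeNode, float]]] = {}

    def walk(node: TreeNode, acc: float, path: list[TreeNode]) -> None:
        if node.is_leaf:
            dist_to_root[node.name] = acc
            parent_paths[node.name] = list(path)
            return
        for child, length in node.children:
            walk(child, acc + length, path + [child])

    walk(root, 0.0, [root])
    out: dict[tuple[str, str], float] = {}
    names = sorted(dist_to_root)
    for a, b in combinations(names, 2):
        pa, pb = parent_paths[a], parent_paths[b]
        shared = 0
        for x, y in zip(pa, pb):
            if x is y:
                shared += 1
            else:
                break
        # depth of the LCA = sum of branch lengths down the shared prefix
        lca_depth = 0.0
        node = pa[0]
        # recompute by walking: accumulate lengths along shared prefix
        acc = 0.0
        cur = None
        for idx in range(shared):
            nxt = pa[idx]
            if cur is not None:
                for child, length in cur.children:
                    if child is nxt:
                        acc += length
                        break
            cur = nxt
        lca_depth = acc
        out[(a, b)] = dist_to_root[a] + dist_to_root[b] - 2.0 * lca_depth
    return out
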