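"""RGA clustering, paired-NLR detection and pan-RGA partitioning."""

import numpy as np
import pandas as pd
import pytest

from pankiwi.model import FamilyMatrix, Gene, GeneSet, PartitionThresholds
from pankiwi.partition import category_share, summary_from_counts
from pankiwi.rga import (
    cluster_genes,
    clustered_fraction,
    paired_nlr,
    paired_nlr_rates,
    pan_rga,
    pan_rga_summary,
)

from oracles import cluster_union_find


def gene(i, start, end, strand="+", fam="F1", cls="NBS", chrom="Chr01"):
    return Gene(f"g{i}", chrom, start, end, strand, family_id=fam, rga_class=cls)


class TestClustering:
    def test_chaining_spans_beyond_pairwise_reach(self):
        # successive gaps of 150 kb chain into one cluster although the
        # outer genes lie ~300 kb apart
        genes = GeneSet([
            gene(1, 100_000, 105_000),
            gene(2, 255_001, 260_000),   # gap 150,000 to g1
            gene(3, 410_001, 415_000),   # gap 150,000 to g2
        ])
        clusters = cluster_genes(genes, 200_000)
        assert [sorted(g.id for g in c) for c in clusters] == [["g1", "g2", "g3"]]

    def test_gap_boundary(self):
        genes = GeneSet([
            gene(1, 100_000, 105_000),
            gene(2, 305_001, 310_000),   # gap exactly 200,000 -> joins
            gene(3, 510_002, 515_000),   # gap 200,001 -> splits
            gene(4, 520_000, 525_000),
        ])
        clusters = cluster_genes(genes, 200_000)
        got = [sorted(g.id for g in c) for c in clusters]
        assert got == [["g1", "g2"], ["g3", "g4"]]

    def test_families_never_co_cluster(self):
        genes = GeneSet([
            gene(1, 10_000, 12_000, fam="F1"),
            gene(2, 15_000, 17_000, fam="F2"),
            gene(3, 20_000, 22_000, fam="F1"),
            gene(4, 25_000, 27_000, fam="F2"),
        ])
        clusters = cluster_genes(genes, 200_000)
        fams = {c[0].family_id for c in clusters}
        assert fams == {"F1", "F2"}
        for c in clusters:
            assert len({g.family_id for g in c}) == 1

    def test_missing_family_skipped_with_warning(self):
        genes = GeneSet([
            Gene("g1", "Chr01", 1000, 2000, "+"),
            gene(2, 3000, 4000),
            gene(3, 6000, 7000),
        ])
        with pytest.warns(UserWarning, match="lack family_id"):
            clusters = cluster_genes(genes, 200_000)
        assert [sorted(g.id for g in c) for c in clusters] == [["g2", "g3"]]

    def test_union_find_oracle_on_random_non_nested_layouts(self, rng):
        for trial in range(20):
            genes, dicts = [], []
            cursor = 1
            for i in range(30):
                cursor += int(rng.integers(1000, 300_000))
                end = cursor + int(rng.integers(1000, 5000))
                fam = f"F{int(rng.integers(1, 4))}"
                chrom = f"Chr0{int(rng.integers(1, 3))}"
                genes.append(gene(i, cursor, end, fam=fam, chrom=chrom))
                dicts.append({"id": f"g{i}", "chrom": chrom, "start": cursor,
                              "end": end, "family": fam})
                cursor = end
            got = sorted(
                sorted(g.id for g in c) for c in cluster_genes(GeneSet(genes), 200_000)
            )
            assert got == cluster_union_find(dicts, 200_000)

    def test_clustered_fraction(self):
        genes = GeneSet(
            [gene(i, 10_000 * (i + 1), 10_000 * (i + 1) + 2000) for i in range(6)]
            + [gene(9, 5_000_000, 5_002_000)]  # isolated
            + [gene(10, 6_000_000, 6_002_000, cls="RLK")]
        )
        clusters = cluster_genes(genes, 200_000)
        assert clustered_fraction(genes, clusters, "NBS") == pytest.approx(
            100.0 * 6 / 7, abs=0.01
        )
        assert clustered_fraction(genes, clusters, "RLK") == 0.0
        assert np.isnan(clustered_fraction(genes, clusters, "RLP"))


class TestPairedNlr:
    def test_divergent_pair_detected(self):
        genes = GeneSet([
            gene(1, 10_000, 13_000, "-", fam="A"),
            gene(2, 18_000, 21_000, "+", fam="B"),
        ])
        pairs = paired_nlr(genes)
        assert [(p["left"], p["right"]) for p in pairs] == [("g1", "g2")]
        assert pairs[0]["gap"] == 18_000 - 13_000 - 1

    def test_tail_to_tail_not_paired(self):
        genes = GeneSet([
            gene(1, 10_000, 13_000, "+", fam="A"),
            gene(2, 18_000, 21_000, "-", fam="B"),
        ])
        assert paired_nlr(genes) == []

    def test_intervening_nbs_gene_breaks_adjacency(self):
        genes = GeneSet([
            gene(1, 10_000, 13_000, "-"),
            gene(2, 14_000, 15_000, "-"),
            gene(3, 18_000, 21_000, "+"),
        ])
        pairs = paired_nlr(genes)
        assert [(p["left"], p["right"]) for p in pairs] == [("g2", "g3")]

    def test_non_nbs_genes_ignored_for_adjacency(self):
        genes = GeneSet([
            gene(1, 10_000, 13_000, "-"),
            gene(2, 14_000, 15_000, "-", cls="RLK"),
            gene(3, 18_000, 21_000, "+"),
        ])
        pairs = paired_nlr(genes)
        assert [(p["left"], p["right"]) for p in pairs] == [("g1", "g3")]

    def test_gap_cap_enforced(self):
        genes = GeneSet([
            gene(1, 10_000, 13_000, "-"),
            gene(2, 60_000, 63_000, "+"),
        ])
        assert paired_nlr(genes, max_gap=20_000) == []
        assert len(paired_nlr(genes, max_gap=60_000)) == 1

    def test_greedy_resolves_triple(self):
        # -,+,+ : the left two pair, the third stays single
        genes = GeneSet([
            gene(1, 10_000, 12_000, "-"),
            gene(2, 14_000, 16_000, "+"),
            gene(3, 18_000, 20_000, "+"),
        ])
        pairs = paired_nlr(genes)
        assert [(p["left"], p["right"]) for p in pairs] == [("g1", "g2")]

    def test_pairs_are_disjoint_and_satisfy_predicates(self, rng):
        genes = []
        cursor = 1
        for i in range(40):
            cursor += int(rng.integers(1000, 30_000))
            end = cursor + int(rng.integers(1000, 4000))
            strand = "-" if rng.random() < 0.5 else "+"
            genes.append(gene(i, cursor, end, strand))
            cursor = end
        gs = GeneSet(genes)
        pairs = paired_nlr(gs, max_gap=20_000)
        used = [g for p in pairs for g in (p["left"], p["right"])]
        assert len(used) == len(set(used))
        by_id = {g.id: g for g in genes}
        ordered = sorted(genes, key=lambda g: g.start)
        for p in pairs:
            left, right = by_id[p["left"]], by_id[p["right"]]
            assert (left.strand, right.strand) == ("-", "+")
            assert p["gap"] <= 20_000
            i = ordered.index(left)
            assert ordered[i + 1] is right

    def test_missing_strand_is_error(self):
        genes = GeneSet([Gene("g1", "Chr01", 1000, 2000, ".", rga_class="NBS")])
        with pytest.raises(ValueError, match="without strand"):
            paired_nlr(genes)

    def test_rates_report_both_denominators(self):
        genes = GeneSet([
            gene(1, 10_000, 12_000, "-"), gene(2, 14_000, 16_000, "+"),
            gene(3, 500_000, 502_000, "+"), gene(4, 900_000, 902_000, "+"),
        ])
        pairs = paired_nlr(genes)
        rates = paired_nlr_rates(genes, pairs)
        assert rates["genes_in_pairs_pct"] == 50.00
        assert rates["pairs_per_nbs_pct"] == 25.00


class TestPanRga:
    def test_published_style_family_totals(self):
        fam = {"core": 263, "softcore": 223, "dispensable": 623, "cloud": 317}
        df = summary_from_counts(fam)
        assert df.loc[df.category == "total", "n_families"].item() == 1_426

    def test_published_style_gene_shares(self):
        # per-class totals: NBS + RLK + RLP + TM-CC = total RGAs
        total = 2_626 + 11_495 + 1_624 + 3_113
        assert total == 18_858
        genes = {"core": 7_893, "softcore": 5_486, "dispensable": 5_136,
                 "cloud": total - 7_893 - 5_486 - 5_136}
        assert category_share(genes, ["core"]) == 41.85
        assert category_share(genes, ["softcore"]) == 29.09
        # 5,136/18,858 = 27.2351%: half-up rounding gives 27.24 where a
        # truncating report would print 27.23
        assert category_share(genes, ["dispensable"]) == pytest.approx(27.23, abs=0.01)

    def test_universal_families_are_all_core(self):
        counts = pd.DataFrame(
            np.ones((4, 15), dtype=int),
            index=[f"R{i}" for i in range(4)],
            columns=[f"a{j}" for j in range(15)],
        )
        result, per_class = pan_rga(
            FamilyMatrix(counts),
            class_of_family={f"R{i}": "NBS" for i in range(4)},
        )
        assert result.family_counts["core"] == 4
        summary = pan_rga_summary(result)
        assert summary.loc[summary.category == "core", "family_pct"].item() == 100.00
        assert per_class.loc[per_class.rga_class == "NBS", "core_pct"].item() == 100.00

    def test_totals_conserve_across_classes(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 3, size=(30, 15)),
            index=[f"R{i}" for i in range(30)],
            columns=[f"a{j}" for j in range(15)],
        )
        counts = counts[counts.sum(axis=1) >= 1]
        classes = {f: ["NBS", "RLK", "RLP", "TM-CC"][i % 4]
                   for i, f in enumerate(counts.index)}
        m = FamilyMatrix(counts)
        result, per_class = pan_rga(m, class_of_family=classes)
        assert per_class["n_genes"].sum() == int(counts.values.sum())
        assert sum(result.gene_counts.values()) == int(counts.values.sum())
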