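"""SV context annotation, hotspot scan, group frequencies, favored
screen, hotspot gene classing and genotype filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pankiwi.model import Gene, GeneSet, GroupAssignment, RegionSet, Variant, VariantCohort
from pankiwi.sv import (
    annotate_sv_context,
    call_sv_hotspots,
    classify_genes_by_hotspot,
    context_summary,
    deg_fraction_by_class,
    favored_svs,
    filter_sv_genotype_matrix,
    group_sv_frequencies,
    sv_window_counts,
)

from conftest import make_cohort, two_group_assignment
from oracles import favored as favored_oracle
from oracles import passes_filters, sv_context


def sv_at(chrom, pos, length=60, vtype="DEL", n=2, vid=None):
    return Variant(chrom, pos, vtype, length, np.zeros(n, dtype=np.int16), vid)


class TestContextAnnotation:
    def test_exon_beats_nearby_gene_flank(self, simple_genes):
        # inside gA's second exon AND within 1 kb upstream region of nothing else
        cohort = VariantCohort([sv_at("Chr01", 11_600)], ["s1", "s2"])
        ctx = annotate_sv_context(cohort, simple_genes)
        assert ctx.iloc[0] == "exon"

    def test_intron_between_exons(self, simple_genes):
        cohort = VariantCohort([sv_at("Chr01", 10_600)], ["s1", "s2"])
        assert annotate_sv_context(cohort, simple_genes).iloc[0] == "intron"

    def test_upstream_of_minus_strand_gene_is_past_its_end(self, simple_genes):
        # gB is minus-strand [20000,23000]: 5' flank lies at [23001,24000]
        cohort = VariantCohort([sv_at("Chr01", 23_500, vtype="INS")], ["s1", "s2"])
        assert annotate_sv_context(cohort, simple_genes).iloc[0] == "upstream"

    def test_downstream_of_minus_strand_gene_is_before_start(self, simple_genes):
        cohort = VariantCohort([sv_at("Chr01", 19_500, vtype="INS")], ["s1", "s2"])
        assert annotate_sv_context(cohort, simple_genes).iloc[0] == "downstream"

    def test_no_exon_models_collapse_to_genic_with_warning(self):
        genes = GeneSet([Gene("g1", "Chr01", 1000, 2000, "+")])
        cohort = VariantCohort([sv_at("Chr01", 1500)], ["s1", "s2"])
        with pytest.warns(UserWarning, match="genic"):
            ctx = annotate_sv_context(cohort, genes)
        assert ctx.iloc[0] == "genic"

    def test_matches_brute_force_on_random_layouts(self, rng):
        genes, dicts = [], []
        pos = 1000
        for i in range(12):
            start = pos + int(rng.integers(0, 3000))
            end = start + int(rng.integers(500, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(start, end + 1), 2 * n_ex, replace=False))
            exons = [(int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n_ex)]
            genes.append(Gene(f"g{i}", "Chr01", start, end, strand, exons=exons))
            dicts.append({"chrom": "Chr01", "start": start, "end": end,
                          "strand": strand, "exons": exons})
            pos = end
        geneset = GeneSet(genes)
        records = []
        for j in range(150):
            p = int(rng.integers(1, pos + 3000))
            vtype = ["INS", "DEL", "INV"][int(rng.integers(0, 3))]
            length = int(rng.integers(50, 2500))
            records.append(sv_at("Chr01", p, length, vtype, vid=f"sv{j}"))
        records.sort(key=lambda v: v.pos)
        cohort = VariantCohort(records, ["s1", "s2"])
        got = annotate_sv_context(cohort, geneset)
        for v in records:
            assert got[v.id] == sv_context(v.span(), "Chr01", dicts), v.id

    def test_categories_partition_and_sum_to_hundred(self, simple_genes, rng):
        records = sorted(
            (sv_at("Chr01", int(p), vid=f"s{i}")
             for i, p in enumerate(rng.integers(1, 30_000, size=60))),
            key=lambda v: v.pos,
        )
        cohort = VariantCohort(records, ["s1", "s2"])
        summary = context_summary(annotate_sv_context(cohort, simple_genes))
        assert summary["n"].sum() == 60
        assert summary["pct"].sum() == pytest.approx(100.0, abs=0.05)


class TestWindowCounts:
    def test_interior_position_falls_in_five_overlapping_windows(self):
        cohort = VariantCohort([sv_at("Chr01", 510_000)], ["s1", "s2"])
        track = sv_window_counts(cohort, window=100_000, step=20_000,
                                 chrom_lengths={"Chr01": 1_000_000})
        hit = track.windows[track.windows["value"] > 0]
        assert len(hit) == 5  # window/step = 100k/20k
        for w in hit.itertuples():
            assert w.start <= 510_000 <= w.end

    def test_empty_cohort_all_zero(self):
        cohort = VariantCohort([], ["s1"])
        track = sv_window_counts(cohort, chrom_lengths={"Chr01": 400_000})
        assert (track.windows["value"] == 0).all()

    def test_uniform_density_gives_constant_interior(self):
        records = [sv_at("Chr01", p, vid=f"v{p}") for p in range(10_000, 990_000, 20_000)]
        cohort = VariantCohort(records, ["s1", "s2"])
        track = sv_window_counts(cohort, chrom_lengths={"Chr01": 1_000_000})
        interior = track.windows.iloc[4:-5]["value"]
        assert interior.nunique() == 1


class TestHotspots:
    def test_two_hundred_distinct_windows_select_ten(self):
        # one window per chromosome so merging cannot fuse selections
        rows = [(f"c{i:03d}", 1, 100_000, float(i + 1), 1) for i in range(200)]
        track_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_sites"])
        from pankiwi.model import WindowTrack

        regions = call_sv_hotspots(WindowTrack(track_df, 100_000, 100_000), 95)
        assert len(regions) == 10
        assert {c for c, _, _ in regions.intervals} == {f"c{i:03d}" for i in range(190, 200)}

    def test_overlapping_selected_windows_chain_merge(self):
        rows = [("c1", 1 + i * 20_000, 100_000 + i * 20_000, v, 1)
                for i, v in enumerate([9.0, 10.0, 0, 0, 0, 0, 0, 0, 0, 0])]
        from pankiwi.model import WindowTrack

        track = WindowTrack(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "value", "n_sites"]), 100_000, 20_000)
        regions = call_sv_hotspots(track, 75)
        assert regions.intervals == [("c1", 1, 120_000)]

    def test_constant_track_none(self):
        rows = [("c1", 1 + i * 20_000, 100_000 + i * 20_000, 4.0, 1) for i in range(30)]
        from pankiwi.model import WindowTrack

        track = WindowTrack(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "value", "n_sites"]), 100_000, 20_000)
        assert len(call_sv_hotspots(track, 95)) == 0


class TestGroupFrequencies:
    def test_allele_counting(self):
        samples, ga = two_group_assignment(4, 2)
        cohort = make_cohort([[2, 1, 0, 0, 1, 1]], sample_ids=samples, vtype="DEL")
        freqs = group_sv_frequencies(cohort, ga)
        assert freqs.loc["v1", "A"] == pytest.approx(3 / 8)
        assert freqs.loc["v1", "B"] == pytest.approx(2 / 4)

    def test_all_missing_group_is_na(self):
        samples, ga = two_group_assignment(2, 2)
        cohort = make_cohort([[-1, -1, 0, 1]], sample_ids=samples, vtype="INS")
        freqs = group_sv_frequencies(cohort, ga)
        assert np.isnan(freqs.loc["v1", "A"])
        assert freqs.loc["v1", "B"] == pytest.approx(0.25)

    def test_carrier_mode(self):
        samples, ga = two_group_assignment(4, 2)
        cohort = make_cohort([[2, 1, 0, 0, 0, 0]], sample_ids=samples, vtype="DEL")
        freqs = group_sv_frequencies(cohort, ga, mode="carrier")
        assert freqs.loc["v1", "A"] == pytest.approx(0.5)

    def test_matches_brute_force_tally(self, rng):
        samples, ga = two_group_assignment(5, 4)
        rows = rng.choice([0, 1, 2, -1], size=(40, 9)).tolist()
        cohort = make_cohort(rows, sample_ids=samples, vtype="DEL")
        freqs = group_sv_frequencies(cohort, ga)
        for i, row in enumerate(rows):
            for g, sl in (("A", slice(0, 5)), ("B", slice(5, 9))):
                obs = [d for d in row[sl] if d >= 0]
                want = sum(obs) / (2 * len(obs)) if obs else float("nan")
                got = freqs.iloc[i][g]
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)

    def test_invariant_to_sample_order(self, rng):
        samples, ga = two_group_assignment(3, 3)
        rows = rng.choice([0, 1, 2], size=(10, 6)).tolist()
        cohort = make_cohort(rows, sample_ids=samples, vtype="DEL")
        perm = [3, 0, 5, 1, 4, 2]
        cohort_p = make_cohort(
            [[r[i] for i in perm] for r in rows],
            sample_ids=[samples[i] for i in perm], vtype="DEL",
        )
        pd.testing.assert_frame_equal(
            group_sv_frequencies(cohort, ga), group_sv_frequencies(cohort_p, ga)
        )


class TestFavoredScreen:
    def test_clear_favored_case(self):
        freqs = pd.DataFrame({"LG": [0.75], "MG1": [0.0], "MG2": [0.02]}, index=["sv1"])
        assert favored_svs(freqs, "LG") == ["sv1"]

    def test_boundary_is_strict(self):
        freqs = pd.DataFrame({"LG": [0.50], "MG1": [0.0], "MG2": [0.0]}, index=["sv1"])
        assert favored_svs(freqs, "LG") == []
        freqs2 = pd.DataFrame({"LG": [0.51], "MG1": [0.05], "MG2": [0.0]}, index=["sv1"])
        assert favored_svs(freqs2, "LG") == []

    def test_grid_enumeration_matches_rule(self):
        grid = [0.0, 0.04, 0.05, 0.5, 0.51, 1.0]
        rows = list(itertools.product(grid, repeat=3))
        freqs = pd.DataFrame(rows, columns=["LG", "MG1", "MG2"],
                             index=[f"sv{i}" for i in range(len(rows))])
        for focal in ("LG", "MG1", "MG2"):
            got = set(favored_svs(freqs, focal))
            want = {
                f"sv{i}" for i, r in enumerate(rows)
                if favored_oracle(dict(zip(["LG", "MG1", "MG2"], r)), focal)
            }
            assert got == want

    def test_na_policies(self):
        freqs = pd.DataFrame(
            {"LG": [0.9, 0.9], "MG1": [np.nan, 0.0], "MG2": [0.0, np.nan]},
            index=["sv1", "sv2"],
        )
        assert favored_svs(freqs, "LG") == []  # conservative default
        assert favored_svs(freqs, "LG", na_policy="ignore") == ["sv1", "sv2"]


class TestHotspotGeneClassing:
    def test_single_bp_body_overlap_wins(self):
        genes = GeneSet([Gene("g1", "Chr01", 1000, 2000, "+")])
        hotspots = RegionSet([("Chr01", 2000, 5000)])
        assert classify_genes_by_hotspot(genes, hotspots)["g1"] == "SV-hotspot"

    def test_upstream_only_overlap(self):
        genes = GeneSet([
            Gene("plus", "Chr01", 10_000, 12_000, "+"),
            Gene("minus", "Chr01", 30_000, 32_000, "-"),
        ])
        hotspots = RegionSet([("Chr01", 8_500, 9_000), ("Chr01", 32_500, 33_000)])
        classes = classify_genes_by_hotspot(genes, hotspots, upstream=2000)
        assert classes["plus"] == "SV-hotspot-upstream"
        assert classes["minus"] == "SV-hotspot-upstream"

    def test_brute_force_on_random_layouts(self, rng):
        hotspots = RegionSet.merge(
            (("Chr01", int(s), int(s) + int(rng.integers(1000, 20_000)))
             for s in rng.integers(1, 500_000, size=8))
        )
        genes = []
        for i in range(80):
            start = int(rng.integers(1, 520_000))
            end = start + int(rng.integers(500, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"g{i}", "Chr01", start, end, strand))
        classes = classify_genes_by_hotspot(GeneSet(genes), hotspots, upstream=2000)
        for g in genes:
            body = any(s <= g.end and g.start <= e for _, s, e in hotspots.intervals)
            if g.strand == "+":
                u = (max(g.start - 2000, 1), g.start - 1)
            else:
                u = (g.end + 1, g.end + 2000)
            up = (not body) and u[0] <= u[1] and any(
                s <= u[1] and u[0] <= e for _, s, e in hotspots.intervals
            )
            want = ("SV-hotspot" if body
                    else "SV-hotspot-upstream" if up else "non-SV-hotspot")
            assert classes[g.id] == want


class TestDegFractions:
    def test_percentages(self):
        classes = {f"g{i}": "SV-hotspot" for i in range(10)}
        classes.update({f"h{i}": "non-SV-hotspot" for i in range(4)})
        de = {"heat": {"g0", "g1", "g2", "x"}}
        df = deg_fraction_by_class(classes, de)
        hot = df[(df["class"] == "SV-hotspot")]["deg_pct"].item()
        assert hot == 30.00
        empty = df[(df["class"] == "SV-hotspot-upstream")]["deg_pct"].item()
        assert np.isnan(empty)

    def test_fold_change_column(self):
        classes = {"g1": "SV-hotspot", "g2": "SV-hotspot"}
        de = {"cu": {"g1", "g2"}}
        fc = {"cu": {"g1": 5.2, "g2": -1.5}}
        df = deg_fraction_by_class(classes, de, fold_changes=fc)
        row = df[df["class"] == "SV-hotspot"].iloc[0]
        assert row["deg_pct"] == 100.00
        assert row["strong_deg_pct"] == 50.00


class TestGenotypeFilter:
    def test_high_missingness_dropped(self):
        rows = [[-1, -1, -1, 1, 1], [0, 1, 1, 1, 0]]
        cohort = make_cohort(rows, vtype="DEL")
        kept = filter_sv_genotype_matrix(cohort, max_missing=0.5, maf=0.05)
        assert [v.id for v in kept.records] == ["v2"]

    def test_maf_boundary_kept(self):
        # 1 alt of 20 alleles = 0.05 exactly -> kept; 0 alt -> dropped
        rows = [[1] + [0] * 9, [0] * 10]
        cohort = make_cohort(rows, vtype="INS")
        kept = filter_sv_genotype_matrix(cohort)
        assert [v.id for v in kept.records] == ["v1"]

    def test_matches_per_record_brute_force(self, rng):
        rows = rng.choice([0, 1, 2, -1], size=(120, 8),
                          p=[0.5, 0.2, 0.1, 0.2]).tolist()
        cohort = make_cohort(rows, vtype="DEL")
        kept = {v.id for v in filter_sv_genotype_matrix(cohort).records}
        want = {f"v{i + 1}" for i, row in enumerate(rows) if passes_filters(row)}
        assert kept == want
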