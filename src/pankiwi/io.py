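"""Readers and writers for the standard formats the pipeline touches.

VCF access goes through cyvcf2; GFF3 through gffutils. All genomic
coordinates are converted to the package's internal 1-based inclusive
convention at this boundary; BED output is 0-based half-open.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    SV_TYPES,
    FamilyMatrix,
    Gene,
    GeneSet,
    GroupAssignment,
    RegionSet,
    Variant,
    VariantCohort,
    WindowTrack,
)

# ---------------------------------------------------------------------------
# orthogroup tables
# ---------------------------------------------------------------------------


def read_orthogroup_table(path: str | os.PathLike, has_header: bool = True,
                          assembly_ids: list[str] | None = None) -> FamilyMatrix:
    """Parse an OrthoFinder-style orthogroup table.

    Tab-separated; first column the family ID, remaining columns
    comma-separated member-gene lists (empty cell = absent). With
    ``has_header=False`` assembly names must be supplied explicitly.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty orthogroup table")
    start = 0
    if has_header:
        header = lines[0].split("\t")
        assembly_ids = header[1:]
        start = 1
    if not assembly_ids:
        raise ValueError("assembly_ids required for headerless tables")
    n_asm = len(assembly_ids)

    fam_ids: list[str] = []
    counts: list[list[int]] = []
    members: dict[tuple[str, str], list[str]] = {}
    seen: set[str] = set()
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = line.split("\t")
        if len(cells) != n_asm + 1:
            raise ValueError(
                f"{path}: line {lineno}: expected {n_asm + 1} columns, got {len(cells)}"
            )
        fam = cells[0]
        if fam in seen:
            raise ValueError(f"{path}: line {lineno}: duplicate family ID {fam!r}")
        seen.add(fam)
        row = []
        for asm, cell in zip(assembly_ids, cells[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()]
            row.append(len(genes))
            if genes:
                members[(fam, asm)] = genes
        fam_ids.append(fam)
        counts.append(row)
    df = pd.DataFrame(counts, index=fam_ids, columns=assembly_ids, dtype=int)
    return FamilyMatrix(df, members)


def write_orthogroup_table(matrix: FamilyMatrix, path: str | os.PathLike) -> None:
    """Inverse of :func:`read_orthogroup_table`. Families whose members
    are unknown are written as anonymous placeholder gene IDs."""
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(matrix.assembly_ids) + "\n")
        for fam in matrix.family_ids:
            cells = []
            for asm in matrix.assembly_ids:
                n = int(matrix.counts.at[fam, asm])
                if matrix.gene_members is not None and (fam, asm) in matrix.gene_members:
                    genes = matrix.gene_members[(fam, asm)]
                else:
                    genes = [f"{asm}.{fam}.g{i + 1}" for i in range(n)]
                cells.append(",".join(genes))
            fh.write(fam + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _dosage_from_alleles(alleles: list[int], alt_index: int = 1) -> int:
    if any(a < 0 for a in alleles):
        return MISSING
    return sum(1 for a in alleles if a == alt_index)


def read_vcf(path: str | os.PathLike, sv_mode: bool = False,
             multiallelic: str = "error") -> VariantCohort:
    """Load a VCF with GT fields into a :class:`VariantCohort`.

    ``sv_mode`` takes type/length from SVTYPE/SVLEN/END; otherwise the
    ref/alt allele lengths decide (equal lengths -> SNP of length 1).
    Multiallelic records are rejected (default) or split to biallelic
    (``multiallelic='split'``), one record per alternate allele.
    """
    if multiallelic not in ("error", "split"):
        raise ValueError("multiallelic must be 'error' or 'split'")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    records: list[Variant] = []
    last_pos: dict[str, int] = {}
    for v in vcf:
        if v.FORMAT is None or "GT" not in v.FORMAT:
            raise ValueError(f"{path}: {v.CHROM}:{v.POS}: record lacks GT")
        if v.CHROM in last_pos and v.POS < last_pos[v.CHROM]:
            raise ValueError(f"{path}: unsorted input at {v.CHROM}:{v.POS}")
        last_pos[v.CHROM] = v.POS
        alts = v.ALT
        if len(alts) > 1 and multiallelic == "error":
            raise ValueError(
                f"{path}: {v.CHROM}:{v.POS}: multiallelic record "
                "(pass multiallelic='split' to decompose)"
            )
        genotypes = v.genotypes  # [[a0, a1, phased], ...]
        for k, alt in enumerate(alts, start=1):
            dosages = np.array(
                [_dosage_from_alleles(gt[:-1], k) for gt in genotypes], dtype=np.int16
            )
            vtype, length = _variant_type_length(v, alt, sv_mode)
            vid = v.ID if v.ID not in (None, ".") else None
            if vid is not None and len(alts) > 1:
                vid = f"{vid}_alt{k}"
            records.append(Variant(v.CHROM, v.POS, vtype, length, dosages, vid))
    return VariantCohort(records, samples)


def _variant_type_length(v, alt: str, sv_mode: bool) -> tuple[str, int]:
    if sv_mode:
        svtype = v.INFO.get("SVTYPE")
        if svtype is None and alt.startswith("<") and alt.endswith(">"):
            svtype = alt[1:-1]
        if svtype not in SV_TYPES:
            raise ValueError(
                f"{v.CHROM}:{v.POS}: cannot determine SV type (got {svtype!r})"
            )
        svlen = v.INFO.get("SVLEN")
        if svlen is not None:
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            length = abs(int(svlen))
        else:
            end = v.INFO.get("END")
            if end is not None:
                length = int(end) - v.POS + 1
            elif not alt.startswith("<"):
                length = max(abs(len(alt) - len(v.REF)), 1)
            else:
                raise ValueError(f"{v.CHROM}:{v.POS}: SV without SVLEN or END")
        return svtype, max(length, 1)
    ref = v.REF
    if len(ref) == len(alt):
        return "SNP", 1
    if len(alt) > len(ref):
        return "INS", len(alt) - len(ref)
    return "DEL", len(ref) - len(alt)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(cohort: VariantCohort, path: str | os.PathLike,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a cohort as VCF 4.2. SVs use symbolic alleles with
    SVTYPE/SVLEN/END; SNPs use placeholder A>T alleles (the pipeline is
    genotype-based and never consults the bases)."""
    chroms = cohort.chroms()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pankiwi\n")
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                length = max(
                    (v.span()[1] for v in cohort.records if v.chrom == c), default=1
                )
                fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for i, v in enumerate(cohort.records):
            vid = v.id or f"var{i + 1}"
            if v.vtype == "SNP":
                ref, alt, info = "A", "T", "."
            else:
                ref, alt = "N", f"<{v.vtype}>"
                svlen = -v.length if v.vtype == "DEL" else v.length
                info = f"SVTYPE={v.vtype};SVLEN={svlen};END={v.span()[1]}"
            gts = "\t".join(_GT_STRINGS[int(d)] for d in v.dosages)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff(path: str | os.PathLike) -> GeneSet:
    """Read gene (and optional exon) features from GFF3.

    Recognised gene attributes: ``ID`` (required), ``family`` and
    ``rga_class`` (optional). Exon features attach to their parent gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, Gene] = {}
    for f in db.features_of_type("gene"):
        gid = f.attributes.get("ID", [f.id])[0]
        if gid in genes:
            raise ValueError(f"{path}: duplicate gene ID {gid!r}")
        family = f.attributes.get("family", [None])[0]
        rga = f.attributes.get("rga_class", [None])[0]
        genes[gid] = Gene(
            gid, f.seqid, f.start, f.end, f.strand or ".",
            family_id=family, rga_class=rga,
        )
    for f in db.features_of_type("exon"):
        parents = f.attributes.get("Parent", [])
        for p in parents:
            if p in genes:
                g = genes[p]
                if g.exons is None:
                    g.exons = []
                g.exons.append((f.start, f.end))
    for g in genes.values():
        if g.exons:
            g.exons.sort()
    return GeneSet(list(genes.values()))


def write_gff(geneset: GeneSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(geneset.genes, key=lambda g: (g.chrom, g.start, g.id)):
            attrs = [f"ID={g.id}"]
            if g.family_id:
                attrs.append(f"family={g.family_id}")
            if g.rga_class:
                attrs.append(f"rga_class={g.rga_class}")
            fh.write(
                f"{g.chrom}\tpankiwi\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                + ";".join(attrs) + "\n"
            )
            for i, (s, e) in enumerate(g.exons or [], start=1):
                fh.write(
                    f"{g.chrom}\tpankiwi\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.exon{i};Parent={g.id}\n"
                )


# ---------------------------------------------------------------------------
# group maps, BED, tracks, trees
# ---------------------------------------------------------------------------


def read_group_map(path: str | os.PathLike) -> GroupAssignment:
    """Two-column TSV: sample, group. Duplicate samples are an error."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sample, group = parts
            if sample in mapping:
                raise ValueError(f"{path}: duplicate sample {sample!r}")
            mapping[sample] = group
    if not mapping:
        raise ValueError(f"{path}: empty group map")
    return GroupAssignment(mapping)


def write_group_map(groups: GroupAssignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.mapping.items():
            fh.write(f"{sample}\t{group}\n")


def write_bed(regions: RegionSet, path: str | os.PathLike) -> None:
    """1-based inclusive -> BED 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_bed(path: str | os.PathLike) -> RegionSet:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, int(start) + 1, int(end)))
    return RegionSet.merge(intervals)


def write_window_track(track: WindowTrack, path: str | os.PathLike) -> None:
    track.windows.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def write_distance_matrix(dm, path: str | os.PathLike) -> None:
    """Square PHYLIP-style matrix: first line taxon count, then one row
    per taxon (name + distances)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.sample_ids)}\n")
        for name, row in zip(dm.sample_ids, dm.values):
            fh.write(name + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def write_newick(tree, path: str | os.PathLike) -> None:
    from .tree import to_newick

    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
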