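import numpy as np
import pytest

from pankiwi.model import Gene, GeneSet, GroupAssignment, Variant, VariantCohort


def make_cohort(dosage_rows, sample_ids=None, chrom="Chr01", start=1000,
                spacing=1000, vtype="SNP", length=None, ids=None):
    """Cohort from a list of per-site dosage lists (-1 = missing)."""
    n = len(dosage_rows[0]) if dosage_rows else 0
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    records = []
    for i, row in enumerate(dosage_rows):
        records.append(
            Variant(
                chrom,
                start + i * spacing,
                vtype,
                length if length is not None else (1 if vtype == "SNP" else 60),
                np.asarray(row, dtype=np.int16),
                ids[i] if ids else f"v{i + 1}",
            )
        )
    return VariantCohort(records, list(sample_ids))


def two_group_assignment(n1, n2, g1="A", g2="B"):
    mapping = {}
    samples = []
    for i in range(n1):
        s = f"{g1}{i + 1}"
        samples.append(s)
        mapping[s] = g1
    for i in range(n2):
        s = f"{g2}{i + 1}"
        samples.append(s)
        mapping[s] = g2
    return samples, GroupAssignment(mapping)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def simple_genes():
    """Two plus-strand and one minus-strand gene with exon models."""
    return GeneSet(
        [
            Gene("gA", "Chr01", 10_000, 12_000, "+", family_id="famX",
                 exons=[(10_000, 10_400), (11_500, 12_000)]),
            Gene("gB", "Chr01", 20_000, 23_000, "-", family_id="famX",
                 exons=[(20_000, 20_500), (22_500, 23_000)]),
            Gene("gC", "Chr02", 5_000, 6_000, "+", family_id="famY",
                 exons=[(5_000, 6_000)]),
        ]
    )
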