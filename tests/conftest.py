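import numpy as np
import pytest

from retropop.types import IndividualRecord, PresenceMatrix, RetroCNVRecord


def make_individuals(spec):
    """spec: list of (pop, subspecies, n) -> IndividualRecords."""
    out = []
    for pop, sub, n in spec:
        for i in range(n):
            out.append(IndividualRecord(f"{pop}_{i + 1:02d}", pop, sub))
    return out


def make_record(rid, chrom="chr1", start=1_000_000, end=1_000_500, gene=None, parental_chrom="chr2"):
    return RetroCNVRecord(
        retrocnv_id=rid,
        parental_gene_id=gene or f"gene_{rid}",
        parental_chrom=parental_chrom,
        insertion_chrom=chrom,
        insertion_start=start,
        insertion_end=end,
    )


@pytest.fixture
def small_presence():
    """3 retroCNVs x 4 individuals in 2 populations."""
    individuals = make_individuals([("P1", "sub1", 2), ("P2", "sub1", 2)])
    records = [make_record(f"r{i}") for i in range(3)]
    values = np.array(
        [
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [0, 1, 1, 1],
        ]
    )
    return PresenceMatrix(individuals, records, values)


@pytest.fixture
def cohort96():
    """The default synthetic 96-individual cohort at a fixed seed."""
    from retropop.synthetic import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(seed=11, n_markers=300))
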