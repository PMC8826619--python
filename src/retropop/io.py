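"""Readers and writers for the tabular, VCF, BED and Newick formats.

Presence table schema (TSV with header)::

    retrocnv_id  parental_gene_id  parental_chrom  insertion_chrom
    insertion_start  insertion_end  <individual_1>  <individual_2> ...

with one 0/1 cell per individual.  Metadata TSV columns:
``individual_id  population_id  subspecies_id``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    GapSet,
    IndividualRecord,
    IntervalSet,
    PresenceMatrix,
    RetroCNVRecord,
    SNPMatrix,
    GenomeTable,
)

PRESENCE_META_COLUMNS = [
    "retrocnv_id",
    "parental_gene_id",
    "parental_chrom",
    "insertion_chrom",
    "insertion_start",
    "insertion_end",
]


def read_metadata(path: str | Path) -> list[IndividualRecord]:
    """Read individual -> population -> subspecies assignments."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "population_id", "subspecies_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path}: missing columns {sorted(missing)}")
    # each population must map to exactly one subspecies
    mapping = df.groupby("population_id")["subspecies_id"].nunique()
    bad = mapping[mapping > 1]
    if not bad.empty:
        raise ValueError(
            f"populations mapped to multiple subspecies: {list(bad.index)}"
        )
    return [
        IndividualRecord(r.individual_id, r.population_id, r.subspecies_id)
        for r in df.itertuples()
    ]


def read_presence_table(
    path: str | Path,
    individuals: list[IndividualRecord] | None = None,
) -> tuple[PresenceMatrix, list[RetroCNVRecord]]:
    """Read a presence/absence table.

    When ``individuals`` is given, its order defines the column order and its
    ids must match the table's individual columns; otherwise individuals are
    created from the header with empty population assignments.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PRESENCE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"presence table {path}: missing columns {missing}")
    ind_cols = [c for c in df.columns if c not in PRESENCE_META_COLUMNS]
    if individuals is not None:
        wanted = [ind.individual_id for ind in individuals]
        absent = set(wanted) - set(ind_cols)
        if absent:
            raise ValueError(f"individuals missing from presence table: {sorted(absent)}")
        ind_cols = wanted
    else:
        individuals = [IndividualRecord(c, "", "") for c in ind_cols]

    records = []
    for row in df.itertuples():
        records.append(
            RetroCNVRecord(
                retrocnv_id=row.retrocnv_id,
                parental_gene_id=row.parental_gene_id,
                parental_chrom=row.parental_chrom,
                insertion_chrom=row.insertion_chrom,
                insertion_start=int(row.insertion_start),
                insertion_end=int(row.insertion_end),
            )
        )
    if df.empty:
        values = np.empty((0, len(ind_cols)), dtype=np.int8)
    else:
        cells = df[ind_cols]
        ok = cells.isin(["0", "1"])
        if not ok.all().all():
            col = ok.all(axis=0).idxmin()
            row_i = int(ok[col].idxmin())
            raise ValueError(
                f"presence table {path}: non-binary cell at retroCNV "
                f"{df.loc[row_i, 'retrocnv_id']!r}, individual {col!r}: "
                f"{cells.loc[row_i, col]!r}"
            )
        values = cells.to_numpy(dtype=np.int8)
    matrix = PresenceMatrix(individuals, records, values)
    return matrix, records


def write_presence_table(matrix: PresenceMatrix, path: str | Path) -> None:
    meta = pd.DataFrame(
        {
            "retrocnv_id": [r.retrocnv_id for r in matrix.retrocnvs],
            "parental_gene_id": [r.parental_gene_id for r in matrix.retrocnvs],
            "parental_chrom": [r.parental_chrom for r in matrix.retrocnvs],
            "insertion_chrom": [r.insertion_chrom for r in matrix.retrocnvs],
            "insertion_start": [r.insertion_start for r in matrix.retrocnvs],
            "insertion_end": [r.insertion_end for r in matrix.retrocnvs],
        }
    )
    body = pd.DataFrame(matrix.values, columns=matrix.individual_ids)
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)


def write_metadata(individuals: list[IndividualRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "individual_id": [i.individual_id for i in individuals],
            "population_id": [i.population_id for i in individuals],
            "subspecies_id": [i.subspecies_id for i in individuals],
        }
    ).to_csv(path, sep="\t", index=False)


def read_vcf_region(
    path: str | Path,
    chrom: str,
    start: int,
    end: int,
    sample_subset: Iterable[str] | None = None,
) -> SNPMatrix:
    """Read biallelic SNP dosages from a VCF region (1-based inclusive).

    Multiallelic and non-SNP records are excluded; missing genotypes are
    encoded as -1.  A region with no sites yields an empty matrix; a region on
    a chromosome unknown to the VCF header raises.
    """
    vcf = VCF(str(path))
    try:
        if chrom not in vcf.seqnames:
            raise ValueError(f"chromosome {chrom!r} not present in VCF {path}")
        samples = list(vcf.samples)
        if sample_subset is not None:
            wanted = list(sample_subset)
            absent = set(wanted) - set(samples)
            if absent:
                raise ValueError(f"samples missing from VCF: {sorted(absent)}")
            cols = [samples.index(s) for s in wanted]
        else:
            wanted = samples
            cols = list(range(len(samples)))

        positions: list[int] = []
        rows: list[np.ndarray] = []
        if str(path).endswith((".gz", ".bgz")):
            iterator = vcf(f"{chrom}:{start}-{end}")
        else:
            iterator = (v for v in vcf if v.CHROM == chrom and start <= v.POS <= end)
        for var in iterator:
            if not (var.CHROM == chrom and start <= var.POS <= end):
                continue
            if len(var.ALT) != 1 or not var.is_snp:
                continue
            gts = np.asarray(var.genotype.array())[:, :2]
            dos = np.where((gts < 0).any(axis=1), MISSING, (gts > 0).sum(axis=1))
            positions.append(var.POS)
            rows.append(dos[cols].astype(np.int8))
        if not positions:
            return SNPMatrix.empty(chrom, wanted)
        return SNPMatrix(chrom, np.asarray(positions), wanted, np.vstack(rows))
    finally:
        vcf.close()


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file into a sorted, merged interval set."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            by_chrom.setdefault(chrom, []).append((start, end))
    return IntervalSet({c: np.asarray(v) for c, v in by_chrom.items()})


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals.chroms():
            for start, end in intervals.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_genome_table(path: str | Path) -> GenomeTable:
    df = pd.read_csv(path, sep="\t")
    return GenomeTable(
        lengths=dict(zip(df["chrom"].astype(str), df["length"].astype(int))),
        multi_exon_gene_counts=dict(
            zip(df["chrom"].astype(str), df["multi_exon_gene_count"].astype(int))
        ),
        autosomes=set(df.loc[df["is_autosome"].astype(bool), "chrom"].astype(str)),
    )


def write_genome_table(genome: GenomeTable, path: str | Path) -> None:
    genome.to_frame().to_csv(path, sep="\t", index=False)


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode, with internal support values as labels.

    Round-trip parsing recovers topology and supports; duplicate tip labels
    are rejected.
    """
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels in tree")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
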