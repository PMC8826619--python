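"""Frequency-group classification and enrichment statistics.

retroCNVs are partitioned by carrier count across the cohort: singletons
(count 1) form the low-frequency group, counts 2-5 the intermediate group
and counts >= 6 the high-frequency group.  The low group represents the most
recent integration events and serves as the baseline retroposition pattern;
an excess of X-derived parental genes in the high group is the population
level analogue of the classic "out-of-X" pattern attributed to adaptive
retention under meiotic sex chromosome inactivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .types import AnnotationSet, ELEMENT_CATEGORIES, GenomeTable, PresenceMatrix, RetroCNVRecord

GROUP_LABELS = ("low", "intermediate", "high")


@dataclass
class ExcessResult:
    """Observed vs expected count with excess fraction and Fisher p."""

    observed: int
    expected: float
    excess_fraction: float
    p_value: float


@dataclass
class FrequencyGroupAssignment:
    groups: dict[str, str]  # retrocnv_id -> low | intermediate | high

    def members(self, group: str) -> list[str]:
        return [rid for rid, g in self.groups.items() if g == group]

    def counts(self) -> dict[str, int]:
        return {g: len(self.members(g)) for g in GROUP_LABELS}


def assign_frequency_groups(presence: PresenceMatrix) -> FrequencyGroupAssignment:
    """Partition retroCNVs into low (1 carrier), intermediate (2-5), high (>= 6)."""
    groups: dict[str, str] = {}
    for rec, count in zip(presence.retrocnvs, presence.carrier_counts):
        count = int(count)
        if count == 0:
            raise ValueError(
                f"retroCNV {rec.retrocnv_id} has zero carriers; a presence data "
                "set cannot contain unobserved alleles"
            )
        if count == 1:
            groups[rec.retrocnv_id] = "low"
        elif count <= 5:
            groups[rec.retrocnv_id] = "intermediate"
        else:
            groups[rec.retrocnv_id] = "high"
    return FrequencyGroupAssignment(groups)


def _x_chrom_names(genome: GenomeTable) -> set[str]:
    return {c for c in genome.chroms if not genome.is_autosome(c)}


def x_chromosome_excess(
    records: list[RetroCNVRecord],
    genome: GenomeTable,
    assignment: FrequencyGroupAssignment,
    group: str,
    alternative: str = "two-sided",
) -> ExcessResult:
    """X-origin excess of one frequency group against the gene-count null.

    The expected X-derived count is the group size times the genome-wide
    fraction of multi-exon protein-coding genes on the X; significance is a
    Fisher exact test on [X-derived, autosome-derived retroCNVs] vs
    [X, autosome gene counts].
    """
    members = set(assignment.members(group))
    if not members:
        raise ValueError(f"frequency group {group!r} is empty")
    recs = [r for r in records if r.retrocnv_id in members]
    for r in recs:
        genome.gene_count(r.parental_chrom)  # raises if missing
    x_chroms = _x_chrom_names(genome)
    obs_x = sum(1 for r in recs if r.parental_chrom in x_chroms)
    obs_auto = len(recs) - obs_x
    genes_x = sum(genome.gene_count(c) for c in genome.chroms if c in x_chroms)
    genes_auto = sum(genome.gene_count(c) for c in genome.chroms if c not in x_chroms)
    expected = len(recs) * genes_x / (genes_x + genes_auto)
    _, p = fisher_exact([[obs_x, obs_auto], [genes_x, genes_auto]], alternative=alternative)
    return ExcessResult(
        observed=obs_x,
        expected=expected,
        excess_fraction=(obs_x - expected) / expected,
        p_value=float(p),
    )


def between_group_x_test(
    records: list[RetroCNVRecord],
    genome: GenomeTable,
    assignment: FrequencyGroupAssignment,
    group_a: str,
    group_b: str,
    alternative: str = "two-sided",
) -> float:
    """Fisher exact p for X-origin counts between two frequency groups."""
    x_chroms = _x_chrom_names(genome)
    table = []
    for group in (group_a, group_b):
        members = set(assignment.members(group))
        if not members:
            raise ValueError(f"frequency group {group!r} is empty")
        recs = [r for r in records if r.retrocnv_id in members]
        x = sum(1 for r in recs if r.parental_chrom in x_chroms)
        table.append([x, len(recs) - x])
    if 0 in np.asarray(table).sum(axis=0) or 0 in np.asarray(table).sum(axis=1):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    _, p = fisher_exact(table, alternative=alternative)
    return float(p)


def element_overlap_fractions(
    records: list[RetroCNVRecord],
    annotations: AnnotationSet,
    genome: GenomeTable,
    assignment: FrequencyGroupAssignment,
    half_width: int = 250,
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group fractions of insertions overlapping each element category.

    Each insertion is represented by the 500 bp interval centred on the
    midpoint of its estimated insertion range (``half_width`` bp each side)
    and tested for >= 1 bp overlap against every category independently — a
    retroCNV inside an intron also overlaps the enclosing protein-coding
    gene, and CDS/UTR are subsets of exon, so categories are not exclusive.

    Returns (fractions, pairwise Fisher p-values) data frames; fraction rows
    are groups, columns categories.  Intervals reaching past a chromosome end
    are clipped with a warning.
    """
    if "intergenic" not in annotations.categories:
        annotations = annotations.with_intergenic(genome)
    by_id = {r.retrocnv_id: r for r in records}
    hits: dict[str, dict[str, list[bool]]] = {
        g: {c: [] for c in ELEMENT_CATEGORIES} for g in GROUP_LABELS
    }
    for rid, group in assignment.groups.items():
        rec = by_id[rid]
        mid = rec.midpoint
        start = mid - half_width
        end = mid + half_width
        length = genome.lengths.get(rec.insertion_chrom)
        if length is not None and (start < 0 or end > length):
            warnings.warn(
                f"retroCNV {rid}: 500 bp interval extends past chromosome end; clipped"
            )
            start = max(0, start)
            end = min(length, end)
        for category in ELEMENT_CATEGORIES:
            hits[group][category].append(
                annotations.get(category).overlaps(rec.insertion_chrom, start, end)
            )

    fractions = pd.DataFrame(
        {
            c: [
                (np.mean(hits[g][c]) if hits[g][c] else np.nan)
                for g in GROUP_LABELS
            ]
            for c in ELEMENT_CATEGORIES
        },
        index=list(GROUP_LABELS),
    )

    rows = []
    pairs = [("low", "intermediate"), ("low", "high"), ("intermediate", "high")]
    for a, b in pairs:
        for category in ELEMENT_CATEGORIES:
            ha, hb = hits[a][category], hits[b][category]
            if not ha or not hb:
                p = np.nan
            else:
                table = [
                    [sum(ha), len(ha) - sum(ha)],
                    [sum(hb), len(hb) - sum(hb)],
                ]
                _, p = fisher_exact(table, alternative=alternative)
            rows.append({"group_a": a, "group_b": b, "category": category, "p_value": p})
    return fractions, pd.DataFrame(rows)
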