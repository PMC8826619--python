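"""Expression and gene-age characterisation of retroCNV parental genes.

Parental genes are the multi-exon protein-coding genes whose mRNA templated a
retrocopy.  Two questions are addressed: are parental genes more broadly and
highly expressed than the multi-exon gene background (retroposition requires
germline transcription), and are they biased toward evolutionarily old
phylostrata (house-keeping genes)?  Expression arrives as an FPKM matrix
(gene x tissue); detectable expression means FPKM > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .frequency import ExcessResult
from .types import RetroCNVRecord


def _wilcoxon_p(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p: exact for small samples, tie-corrected normal
    approximation otherwise."""
    method = "exact" if (len(x) <= 50 and len(y) <= 50 and not _has_ties(x, y)) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


@dataclass
class TissueComparison:
    tissue: str
    focal_fraction: float
    control_fraction_mean: float
    control_fraction_se: float
    wilcoxon_p: float


def expressed_fraction_comparison(
    expr: pd.DataFrame,
    focal_genes: list[str],
    control_universe: list[str],
    n_boot: int = 100,
    seed: int | None = None,
) -> list[TissueComparison]:
    """Per-tissue expressed fraction of focal genes vs a resampled control.

    For each tissue: the fraction of focal genes with FPKM > 0; the mean and
    standard error of that fraction over ``n_boot`` random samples of
    ``len(focal_genes)`` genes from the control universe; and a Wilcoxon
    rank-sum p comparing focal vs control expression levels.
    """
    focal = [g for g in focal_genes if g in expr.index]
    control = [g for g in control_universe if g in expr.index]
    if not focal or not control:
        raise ValueError("focal and control gene sets must intersect the matrix")
    rng = np.random.default_rng(seed)
    out = []
    control_arr = np.asarray(control)
    for tissue in expr.columns:
        fpkm_focal = expr.loc[focal, tissue].to_numpy(dtype=float)
        fpkm_control = expr.loc[control, tissue].to_numpy(dtype=float)
        focal_frac = float((fpkm_focal > 0).mean())
        boot = np.empty(n_boot)
        for b in range(n_boot):
            sample = rng.choice(control_arr, size=len(focal), replace=True)
            boot[b] = (expr.loc[sample, tissue].to_numpy(dtype=float) > 0).mean()
        out.append(
            TissueComparison(
                tissue=str(tissue),
                focal_fraction=focal_frac,
                control_fraction_mean=float(boot.mean()),
                control_fraction_se=float(boot.std(ddof=1) / np.sqrt(n_boot)),
                wilcoxon_p=_wilcoxon_p(fpkm_focal, fpkm_control),
            )
        )
    return out


def recurrence_expression_test(
    expr: pd.DataFrame,
    records: list[RetroCNVRecord],
    tissue: str,
) -> tuple[float, float, float]:
    """Compare expression of recurrently retroposed parental genes (>= 2
    distinct insertion alleles) against single-copy sources.

    Each parental gene counts once regardless of its number of insertion
    alleles.  Returns (wilcoxon_p, median_single, median_recurrent).
    """
    if tissue not in expr.columns:
        raise ValueError(f"tissue {tissue!r} absent from expression matrix")
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.parental_gene_id] = counts.get(rec.parental_gene_id, 0) + 1
    single = [g for g, c in counts.items() if c == 1 and g in expr.index]
    recurrent = [g for g, c in counts.items() if c >= 2 and g in expr.index]
    if not single or not recurrent:
        raise ValueError("both single-source and recurrent-source groups must be non-empty")
    x = expr.loc[single, tissue].to_numpy(dtype=float)
    y = expr.loc[recurrent, tissue].to_numpy(dtype=float)
    return _wilcoxon_p(x, y), float(np.median(x)), float(np.median(y))


def age_group_excess(
    focal_genes: list[str],
    ages: dict[str, str],
    control_universe: list[str],
    min_coverage: float = 0.95,
) -> dict[str, ExcessResult]:
    """Observed vs expected parental-gene counts per phylostratum.

    The expectation for each age group is the focal-set size times the
    control universe's proportion in that group.  Focal genes without an age
    assignment are dropped (at most ``1 - min_coverage`` of them); empty
    control strata are skipped with a warning.  Fisher exact p per stratum on
    [focal in/out of stratum] vs [control in/out].
    """
    import warnings
    from scipy.stats import fisher_exact

    focal_aged = [g for g in focal_genes if g in ages]
    if len(focal_aged) < min_coverage * len(focal_genes):
        raise ValueError(
            f"age assignments cover only {len(focal_aged)}/{len(focal_genes)} focal genes"
        )
    dropped = len(focal_genes) - len(focal_aged)
    if dropped:
        warnings.warn(f"{dropped} focal genes lack an age assignment; dropped")
    control_aged = [g for g in control_universe if g in ages]
    strata = sorted({ages[g] for g in control_aged})
    n_focal = len(focal_aged)
    n_control = len(control_aged)
    out: dict[str, ExcessResult] = {}
    for stratum in strata:
        control_in = sum(1 for g in control_aged if ages[g] == stratum)
        if control_in == 0:
            warnings.warn(f"phylostratum {stratum!r} empty in control universe; skipped")
            continue
        obs = sum(1 for g in focal_aged if ages[g] == stratum)
        expected = n_focal * control_in / n_control
        _, p = fisher_exact(
            [[obs, n_focal - obs], [control_in, n_control - control_in]]
        )
        out[stratum] = ExcessResult(
            observed=obs,
            expected=expected,
            excess_fraction=(obs - expected) / expected,
            p_value=float(p),
        )
    return out


def read_age_assignments(path) -> dict[str, str]:
    """Read a two-column gene -> phylostratum TSV (header optional).

    Accepts both GenTree-style labels (``PS1``...) and bare branch numbers,
    which are normalised to ``PS<k>``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.iloc[0, 0].lower() in {"gene_id", "gene", "id"}:
        df = df.iloc[1:]
    out = {}
    for gene, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        label = str(label)
        out[str(gene)] = label if label.upper().startswith("PS") else f"PS{label}"
    return out
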