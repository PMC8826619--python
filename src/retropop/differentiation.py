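"""Population differentiation index (PDI) with a permutation null.

For a binary marker with overall presence frequency P, population frequencies
P_i and relative population sizes F_i = N_i / sum(N_i), the PDI is

    PDI = [ P(1-P) - sum_i F_i P_i (1-P_i) ] / [ P(1-P) ]
        = 1 - sum_i F_i P_i (1-P_i) / ( P(1-P) )

i.e. one minus the ratio of size-weighted within-population binomial variance
to total variance — a fixation-index-equivalent for presence/absence markers.
It is 0 when every population shares the same frequency and 1 when the marker
is fixed within each population it occurs in (no within-population variance).

Significance comes from shuffling individual labels while keeping the
population sizes fixed (the carrier multiset of each marker is preserved),
with an add-one empirical p-value, followed by Benjamini-Hochberg FDR
control across markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import PresenceMatrix

__all__ = [
    "pdi",
    "pdi_vector",
    "pdi_permutation_test",
    "bh_fdr",
    "DifferentiationTest",
    "PDIResults",
]


def _population_indicator(population_ids: np.ndarray) -> tuple[np.ndarray, list[str]]:
    pops = list(dict.fromkeys(population_ids))  # stable order of appearance
    indicator = np.zeros((len(population_ids), len(pops)), dtype=float)
    for j, pop in enumerate(pops):
        indicator[np.asarray(population_ids) == pop, j] = 1.0
    return indicator, pops


def pdi_from_frequencies(P_i: np.ndarray, sizes: np.ndarray) -> float:
    """PDI from per-population frequencies and population sizes."""
    P_i = np.asarray(P_i, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    F_i = sizes / sizes.sum()
    P = float((F_i * P_i).sum())
    total_var = P * (1.0 - P)
    if total_var == 0.0:
        return math.nan
    within = float((F_i * P_i * (1.0 - P_i)).sum())
    return 1.0 - within / total_var


def pdi(presence_row: np.ndarray, population_ids: np.ndarray) -> float:
    """PDI of one marker given each individual's population label.

    Undefined (nan) for markers with overall frequency 0 or 1.
    """
    row = np.asarray(presence_row, dtype=float)
    indicator, _ = _population_indicator(np.asarray(population_ids))
    sizes = indicator.sum(axis=0)
    P_i = row @ indicator / sizes
    return pdi_from_frequencies(P_i, sizes)


def pdi_vector(values: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    """Vectorised PDI for all markers: values (m, n) x indicator (n, pops)."""
    sizes = indicator.sum(axis=0)
    F_i = sizes / sizes.sum()
    P_i = (values @ indicator) / sizes  # (m, pops)
    P = P_i @ F_i
    total_var = P * (1.0 - P)
    within = (F_i * P_i * (1.0 - P_i)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - within / total_var
    out[total_var == 0.0] = np.nan
    return out


def pdi_permutation_test(
    presence: PresenceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    shared_schedule: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for each marker's PDI.

    Each permutation reassigns all individuals to populations at random
    (population sizes unchanged); by default one shared schedule scores every
    marker on the same relabelings.  p = (1 + #{null >= observed}) / (n_perm
    + 1).  Markers with undefined PDI get p = nan.

    Returns (observed PDI vector, p-value vector).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} gives coarse p-values; >= 100 recommended")
    rng = np.random.default_rng(seed)
    values = presence.values.astype(float)
    indicator, _ = _population_indicator(presence.population_of())
    observed = pdi_vector(values, indicator)
    n_ind = values.shape[1]
    exceed = np.zeros(values.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(n_ind) if shared_schedule else None
        if shared_schedule:
            null = pdi_vector(values[:, perm], indicator)
        else:
            null = np.empty(values.shape[0])
            for m in range(values.shape[0]):
                null[m] = pdi_vector(
                    values[m : m + 1, rng.permutation(n_ind)], indicator
                )[0]
        with np.errstate(invalid="ignore"):
            exceed += (null >= observed).astype(float)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[np.isnan(observed)] = np.nan
    return observed, p


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q_values, is_marker flags at q <= alpha).

    nan p-values propagate to nan q and False flags.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    flags = np.zeros(p.size, dtype=bool)
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        flags[ok] = q[ok] <= alpha
    return q, flags


class DifferentiationTest:
    """Model: PDI-based detection of population-differentiating markers.

    Built from a presence matrix whose individuals carry population labels;
    ``fit`` runs the observed PDIs, the label-shuffling null and BH-FDR and
    returns a :class:`PDIResults`.
    """

    def __init__(self, presence: PresenceMatrix) -> None:
        if not all(ind.population_id for ind in presence.individuals):
            raise ValueError("every individual needs a population label")
        self.presence = presence

    @classmethod
    def from_files(cls, presence_path, metadata_path) -> "DifferentiationTest":
        from . import io as rio

        individuals = rio.read_metadata(metadata_path)
        matrix, _ = rio.read_presence_table(presence_path, individuals)
        return cls(matrix)

    def fit(
        self,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: int | None = None,
        shared_schedule: bool = True,
    ) -> "PDIResults":
        observed, p = pdi_permutation_test(
            self.presence, n_perm=n_perm, seed=seed, shared_schedule=shared_schedule
        )
        q, flags = bh_fdr(p, alpha=alpha)
        return PDIResults(
            model=self,
            pdi=observed,
            p_values=p,
            q_values=q,
            is_marker=flags,
            n_perm=n_perm,
            alpha=alpha,
        )


@dataclass
class PDIResults:
    """Per-marker PDI estimates with permutation p, BH q and marker flags."""

    model: DifferentiationTest
    pdi: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    is_marker: np.ndarray
    n_perm: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "retrocnv_id": self.model.presence.retrocnv_ids,
                "pdi": self.pdi,
                "p_value": self.p_values,
                "q_value": self.q_values,
                "is_marker": self.is_marker,
            }
        )

    @property
    def n_markers_flagged(self) -> int:
        return int(self.is_marker.sum())

    def summary(self) -> str:
        n = len(self.pdi)
        testable = int((~np.isnan(self.pdi)).sum())
        lines = [
            "Population Differentiation Index (PDI) permutation test",
            "=" * 56,
            f"retroCNV markers:        {n}",
            f"testable (polymorphic):  {testable}",
            f"permutations:            {self.n_perm}",
            f"FDR threshold:           {self.alpha}",
            f"differentiation markers: {self.n_markers_flagged} "
            f"({100.0 * self.n_markers_flagged / max(1, n):.1f}% of all markers)",
            f"median PDI:              {np.nanmedian(self.pdi):.4f}",
        ]
        return "\n".join(lines)
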