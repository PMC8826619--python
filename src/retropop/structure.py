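"""Individual distances, PCA and population trees from presence spectra.

The presence-fraction spectrum — for each population, the fraction of its
individuals carrying each marker — is the character matrix for a
neighbor-joining tree over populations (Euclidean distance between fraction
vectors), with split confidence from bootstrap resampling of markers.  The
same machinery builds a comparison tree from derived-SNP carrier fractions
after LD pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .popgen import ld_prune
from .types import PresenceMatrix, SNPMatrix

__all__ = [
    "pairwise_retrocnv_distance",
    "presence_pca",
    "presence_spectrum",
    "snp_population_spectrum",
    "nj_tree",
    "bootstrap_supports",
    "tree_splits",
    "PresenceSpectrum",
    "PopulationTree",
    "TreeResult",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_retrocnv_distance(presence: PresenceMatrix) -> DistanceMatrix:
    """Distance between individuals: fraction of retroCNVs with differing
    presence status, i.e. normalised Hamming distance of the 0/1 columns."""
    if presence.n_retrocnvs == 0:
        raise ValueError("cannot compute distances with zero retroCNVs")
    cols = presence.values.T.astype(np.int16)  # (individuals, markers)
    diff = (cols[:, None, :] != cols[None, :, :]).mean(axis=2)
    return DistanceMatrix(presence.individual_ids, diff)


def presence_pca(
    presence: PresenceMatrix,
    n_components: int = 2,
    subspecies: str | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores of individuals on the column-centred presence matrix.

    ``subspecies`` restricts the decomposition to that subspecies' individuals
    (the inset-style rerun).  Returns (scores frame indexed by individual,
    explained-variance ratios).
    """
    from sklearn.decomposition import PCA

    mask = np.ones(presence.n_individuals, dtype=bool)
    if subspecies is not None:
        mask = presence.subspecies_of() == subspecies
    X = presence.values.T[mask].astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 markers")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("presence matrix is constant; PCA undefined")
    pca = PCA(n_components=min(n_components, min(X.shape) - 1))
    scores = pca.fit_transform(X - X.mean(axis=0))
    ids = np.asarray(presence.individual_ids)[mask]
    frame = pd.DataFrame(
        scores, index=ids, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    return frame, pca.explained_variance_ratio_


@dataclass
class PresenceSpectrum:
    """Population x marker matrix of presence fractions in [0, 1]."""

    populations: list[str]
    sizes: np.ndarray
    fractions: np.ndarray  # (populations, markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.populations)


def presence_spectrum(presence: PresenceMatrix) -> PresenceSpectrum:
    """Per-population carrier fractions for every retroCNV."""
    pops = presence.population_of()
    if (pops == "").any():
        raise ValueError("every individual needs a population label")
    unique = list(dict.fromkeys(pops))
    sizes = np.asarray([(pops == p).sum() for p in unique])
    fractions = np.vstack(
        [presence.values[:, pops == p].mean(axis=1) for p in unique]
    )
    return PresenceSpectrum(unique, sizes, fractions)


def snp_population_spectrum(
    snps: SNPMatrix,
    population_ids: np.ndarray,
    prune: bool = True,
    prune_kwargs: dict | None = None,
) -> PresenceSpectrum:
    """Per-population fraction of individuals carrying the derived allele.

    Carrier status is dosage >= 1 (heterozygous and homozygous carriers count
    equally); sites carry derived-allele orientation by construction of the
    input.  LD pruning (r^2 >= 0.2 in 500-SNP windows stepping by 100) is
    applied first unless ``prune=False``.
    """
    if prune:
        keep = ld_prune(snps, **(prune_kwargs or {}))
        snps = SNPMatrix(
            snps.chrom, snps.positions[keep], list(snps.sample_ids), snps.dosages[keep]
        )
    pops = np.asarray(population_ids)
    unique = list(dict.fromkeys(pops))
    sizes = np.asarray([(pops == p).sum() for p in unique])
    carrier = (snps.dosages >= 1) & (snps.dosages != -1)
    fractions = np.vstack([carrier[:, pops == p].mean(axis=1) for p in unique])
    return PresenceSpectrum(unique, sizes, fractions)


def _euclidean_dm(spectrum: PresenceSpectrum) -> DistanceMatrix:
    X = spectrum.fractions
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(list(spectrum.populations), d)


def _nj_from_dm(dm: DistanceMatrix) -> TreeNode:
    skdm = SkbioDM(dm.values, ids=dm.labels)
    return nj(skdm)


def tree_splits(tree: TreeNode, tip_set: frozenset[str] | None = None) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each as the smaller-or-
    canonical side's frozenset of tip names."""
    tips = frozenset(t.name for t in tree.tips()) if tip_set is None else tip_set
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            other = tips - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def nj_tree(spectrum_or_dm) -> "TreeResult":
    """Neighbor-joining tree over populations.

    Accepts a :class:`PresenceSpectrum` (Euclidean distances between
    population fraction vectors) or a precomputed :class:`DistanceMatrix`.
    Negative branch lengths are clamped to zero with the deficit transferred
    to the adjacent branch (standard NJ post-processing).
    """
    if isinstance(spectrum_or_dm, PresenceSpectrum):
        dm = _euclidean_dm(spectrum_or_dm)
    else:
        dm = spectrum_or_dm
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _nj_from_dm(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            deficit = node.length
            node.length = 0.0
            sibs = [s for s in node.siblings() if s.length is not None]
            if sibs:
                sibs[0].length = max(0.0, sibs[0].length + deficit)
    return TreeResult(tree=tree, distance_matrix=dm)


def bootstrap_supports(
    spectrum: PresenceSpectrum,
    n_boot: int = 1000,
    seed: int | None = None,
) -> "TreeResult":
    """NJ tree with split supports from bootstrap resampling of markers.

    Markers (columns of the spectrum) are resampled with replacement
    ``n_boot`` times, the tree rebuilt each time, and each original split's
    recovery counted.  Splits recovered in >= 80% of replicates are the
    high-confidence ones.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(spectrum.populations) < 4:
        raise ValueError("bootstrap supports need >= 4 populations (no internal splits otherwise)")
    result = nj_tree(spectrum)
    tips = frozenset(spectrum.populations)
    original = tree_splits(result.tree, tips)
    counts = {s: 0 for s in original}
    rng = np.random.default_rng(seed)
    n_markers = spectrum.fractions.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_markers, size=n_markers)
        boot = PresenceSpectrum(
            spectrum.populations, spectrum.sizes, spectrum.fractions[:, cols]
        )
        boot_splits = tree_splits(nj_tree(boot).tree, tips)
        for s in original:
            if s in boot_splits:
                counts[s] += 1
    result.supports = {s: c for s, c in counts.items()}
    result.n_boot = n_boot
    return result


@dataclass
class TreeResult:
    """An unrooted population tree with optional per-split bootstrap counts."""

    tree: TreeNode
    distance_matrix: DistanceMatrix
    supports: dict[frozenset, int] | None = None
    n_boot: int = 0

    def support_percent(self) -> dict[frozenset, float]:
        if not self.supports or not self.n_boot:
            return {}
        return {s: 100.0 * c / self.n_boot for s, c in self.supports.items()}

    def high_confidence_splits(self, threshold: float = 80.0) -> list[frozenset]:
        return [s for s, pct in self.support_percent().items() if pct >= threshold]

    def newick(self) -> str:
        tree = self.tree.copy()
        if self.supports and self.n_boot:
            pct = self.support_percent()
            tips = frozenset(t.name for t in tree.tips())
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                key = min(side, tips - side, key=lambda s: (len(s), sorted(s)))
                if key in pct:
                    node.name = f"{pct[key]:.0f}"
        return str(tree).strip()

    def summary(self) -> str:
        lines = [
            f"Neighbor-joining population tree ({len(self.distance_matrix.labels)} tips)",
            "=" * 56,
            self.tree.ascii_art(),
        ]
        if self.supports:
            lines.append(f"bootstrap replicates: {self.n_boot}")
            for s, pct in sorted(self.support_percent().items(), key=lambda kv: -kv[1]):
                mark = "*" if pct >= 80 else " "
                lines.append(f" {mark} {sorted(s)}: {pct:.1f}%")
        return "\n".join(lines)


class PopulationTree:
    """Model: population phylogeny from a presence matrix.

    ``fit`` computes the presence-fraction spectrum, the NJ tree and
    bootstrap supports, returning a :class:`TreeResult`.
    """

    def __init__(self, presence: PresenceMatrix) -> None:
        self.presence = presence

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> TreeResult:
        spectrum = presence_spectrum(self.presence)
        if len(spectrum.populations) >= 4:
            return bootstrap_supports(spectrum, n_boot=n_boot, seed=seed)
        return nj_tree(spectrum)
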