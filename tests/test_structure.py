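"""Distances, PCA, presence spectra, NJ trees and bootstrap supports.

The NJ oracle is additive-tree inversion: distances generated by summing
branch lengths along paths of a known random topology must be inverted back
to that topology exactly.
"""

import itertools

import numpy as np
import pytest

from retropop.structure import (
    DistanceMatrix,
    PopulationTree,
    bootstrap_supports,
    nj_tree,
    pairwise_retrocnv_distance,
    presence_pca,
    presence_spectrum,
    snp_population_spectrum,
    tree_splits,
)
from retropop.synthetic import SimConfig, simulate_cohort
from retropop.types import PresenceMatrix, SNPMatrix

from conftest import make_individuals, make_record


def random_additive_tree(n_taxa, rng):
    """Random binary tree via sequential joins; returns (distance matrix,
    split set) computed purely from path lengths — an NJ-independent oracle."""
    import networkx as nx

    g = nx.Graph()
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = list(labels)
    g.add_nodes_from(nodes)
    nxt = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        internal = f"i{nxt}"
        nxt += 1
        g.add_edge(nodes[i], internal, weight=float(rng.uniform(0.5, 2.0)))
        g.add_edge(nodes[j], internal, weight=float(rng.uniform(0.5, 2.0)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [internal]
    g.add_edge(nodes[0], nodes[1], weight=float(rng.uniform(0.5, 2.0)))

    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    dm = np.zeros((n_taxa, n_taxa))
    for a, b in itertools.combinations(range(n_taxa), 2):
        dm[a, b] = dm[b, a] = dist[labels[a]][labels[b]]

    tips = frozenset(labels)
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        comp = next(c for c in nx.connected_components(h) if u in c)
        side = frozenset(x for x in comp if x in tips)
        if 1 < len(side) < n_taxa - 1:
            splits.add(min(side, tips - side, key=lambda s: (len(s), sorted(s))))
    return DistanceMatrix(labels, dm), splits


class TestDistance:
    def test_identical_and_complementary(self):
        individuals = make_individuals([("P", "s", 3)])
        records = [make_record(f"r{i}") for i in range(10)]
        values = np.zeros((10, 3), dtype=int)
        values[:, 0] = values[:, 1] = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        values[:, 2] = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
        pm = PresenceMatrix(individuals, records, values)
        d = pairwise_retrocnv_distance(pm)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_hamming_oracle(self, small_presence):
        d = pairwise_retrocnv_distance(small_presence)
        cols = small_presence.values.T
        for i, j in itertools.combinations(range(4), 2):
            assert d.values[i, j] == pytest.approx((cols[i] != cols[j]).mean())

    def test_symmetric_zero_diagonal_bounded(self, cohort96):
        d = pairwise_retrocnv_distance(cohort96).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_zero_markers_error(self):
        individuals = make_individuals([("P", "s", 3)])
        pm = PresenceMatrix(individuals, [], np.empty((0, 3)))
        with pytest.raises(ValueError, match="zero retroCNVs"):
            pairwise_retrocnv_distance(pm)


class TestPCA:
    def _two_block(self):
        individuals = make_individuals([("P1", "s", 4), ("P2", "s", 4)])
        records = [make_record(f"r{i}") for i in range(6)]
        values = np.zeros((6, 8), dtype=int)
        values[:3, :4] = 1  # block 1 carries markers 0-2
        values[3:, 4:] = 1  # block 2 carries markers 3-5
        values[5, 0] = 1  # avoid perfectly constant pattern? keep blocks clean
        values[5, 0] = 0
        return PresenceMatrix(individuals, records, values)

    def test_two_blocks_separate_on_pc1(self):
        pm = self._two_block()
        scores, _ = presence_pca(pm)
        pc1 = scores["PC1"].to_numpy()
        assert np.allclose(pc1[:4], pc1[0])
        assert np.allclose(pc1[4:], pc1[4])
        assert abs(pc1[0] - pc1[4]) > 0

    def test_marker_order_invariance_up_to_sign(self, cohort96):
        scores_a, _ = presence_pca(cohort96)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort96.n_retrocnvs)
        pm2 = PresenceMatrix(
            cohort96.individuals,
            [cohort96.retrocnvs[i] for i in perm],
            cohort96.values[perm],
        )
        scores_b, _ = presence_pca(pm2)
        for col in scores_a.columns:
            a, b = scores_a[col].to_numpy(), scores_b[col].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_eigenvalue_sum_identity(self, cohort96):
        from sklearn.decomposition import PCA

        X = cohort96.values.T.astype(float)
        Xc = X - X.mean(axis=0)
        pca = PCA()
        pca.fit(Xc)
        total_var = Xc.var(axis=0, ddof=1).sum()
        assert pca.explained_variance_.sum() == pytest.approx(total_var)
        assert pca.explained_variance_ratio_.sum() == pytest.approx(1.0)

    def test_constant_matrix_error(self):
        individuals = make_individuals([("P", "s", 3)])
        records = [make_record(f"r{i}") for i in range(2)]
        values = np.array([[1, 1, 1], [0, 0, 0]])
        pm = PresenceMatrix(individuals, records, values, allow_fixed=True)
        with pytest.raises(ValueError, match="constant"):
            presence_pca(pm)

    def test_subspecies_restriction(self, cohort96):
        scores, _ = presence_pca(cohort96, subspecies="domesticus")
        subs = {
            ind.individual_id
            for ind in cohort96.individuals
            if ind.subspecies_id == "domesticus"
        }
        assert set(scores.index) == subs


class TestSpectrum:
    def test_fixed_and_singleton_fractions(self):
        individuals = make_individuals([("P1", "s", 10), ("P2", "s", 5)])
        records = [make_record("r0"), make_record("r1")]
        values = np.zeros((2, 15), dtype=int)
        values[0, :10] = 1  # fixed in P1
        values[1, 10] = 1  # singleton in P2
        pm = PresenceMatrix(individuals, records, values)
        spec = presence_spectrum(pm)
        assert spec.fractions[spec.populations.index("P1"), 0] == 1.0
        assert spec.fractions[spec.populations.index("P2"), 0] == 0.0
        assert spec.fractions[spec.populations.index("P2"), 1] == pytest.approx(1 / 5)

    def test_rowsum_consistency(self, cohort96):
        spec = presence_spectrum(cohort96)
        implied = (spec.fractions * spec.sizes[:, None]).sum(axis=0)
        assert np.allclose(implied, cohort96.carrier_counts)

    def test_snp_spectrum_dosage_rule(self):
        pops = np.array(["A", "A", "B", "B"])
        dosages = np.array([[2, 2, 0, 0], [1, 2, 0, 1]], dtype=np.int8)
        snps = SNPMatrix("chr1", np.array([10, 20]), ["a", "b", "c", "d"], dosages)
        spec = snp_population_spectrum(snps, pops, prune=False)
        assert spec.fractions[0, 0] == 1.0  # A fixed at site 1
        # het and hom count the same: site 2 fractions 1.0 (A), 0.5 (B)
        assert spec.fractions[0, 1] == 1.0
        assert spec.fractions[1, 1] == 0.5

    def test_snp_spectrum_pruned_no_high_ld_pair(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=40)
        d = np.vstack([base, base, rng.integers(0, 3, size=(6, 40))]).astype(np.int8)
        snps = SNPMatrix("chr1", np.arange(10, 10 + 80, 10), [f"s{i}" for i in range(40)], d)
        pops = np.array(["A"] * 20 + ["B"] * 20)
        spec = snp_population_spectrum(snps, pops, prune=True)
        assert spec.fractions.shape[1] < 8  # the duplicate was pruned


class TestNJ:
    def test_three_taxa_closed_form(self):
        # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> a=1, b=2, c=3
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        result = nj_tree(dm)
        lengths = {t.name: t.length for t in result.tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(1)
        dm, true_splits = random_additive_tree(4, rng)
        result = nj_tree(dm)
        assert tree_splits(result.tree) == true_splits

    def test_fifty_random_additive_trees_recovered(self):
        """NJ inverts additive distances from random <= 8-taxon trees."""
        rng = np.random.default_rng(2)
        for k in range(50):
            n = int(rng.integers(4, 9))
            dm, true_splits = random_additive_tree(n, rng)
            assert tree_splits(nj_tree(dm).tree) == true_splits, f"trial {k}"

    def test_label_permutation_same_splits(self):
        rng = np.random.default_rng(3)
        dm, _ = random_additive_tree(6, rng)
        perm = rng.permutation(6)
        dm2 = DistanceMatrix([dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)])
        assert tree_splits(nj_tree(dm).tree) == tree_splits(nj_tree(dm2).tree)

    def test_too_few_taxa(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]]))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(dm)


class TestBootstrap:
    def _clade_spectrum(self, fst=0.3, seed=0, n_markers=300):
        """Two deeply separated 2-population clades."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.9, size=n_markers)
        shift = rng.choice([-0.35, 0.35], size=n_markers)
        clade1 = np.clip(p + shift, 0.01, 0.99)
        clade2 = np.clip(p - shift, 0.01, 0.99)
        noise = lambda q: np.clip(q + rng.normal(0, 0.03, size=n_markers), 0, 1)
        fr = np.vstack([noise(clade1), noise(clade1), noise(clade2), noise(clade2)])
        from retropop.structure import PresenceSpectrum

        return PresenceSpectrum(["A1", "A2", "B1", "B2"], np.full(4, 12), fr)

    def test_true_split_highly_supported(self):
        spec = self._clade_spectrum()
        result = bootstrap_supports(spec, n_boot=200, seed=1)
        pct = result.support_percent()
        split = frozenset({"A1", "A2"})
        assert pct[split] >= 95.0

    def test_exchangeable_populations_diffuse_support(self):
        """With no real structure (identical population frequencies plus iid
        sampling noise) split supports stay diffuse: the mean is far below the
        80% confidence mark and confident splits are rare across 20 runs."""
        from retropop.structure import PresenceSpectrum

        rng = np.random.default_rng(4)
        pcts = []
        for run in range(20):
            fr = np.tile(rng.uniform(0.2, 0.8, size=100), (5, 1))
            fr = np.clip(fr + rng.normal(0, 0.05, size=fr.shape), 0, 1)
            spec = PresenceSpectrum([f"P{i}" for i in range(5)], np.full(5, 10), fr)
            result = bootstrap_supports(spec, n_boot=50, seed=run)
            pcts.extend(result.support_percent().values())
        assert np.mean(pcts) < 65.0
        assert np.mean([p >= 80 for p in pcts]) <= 0.2

    def test_seed_determinism(self):
        spec = self._clade_spectrum()
        a = bootstrap_supports(spec, n_boot=50, seed=9)
        b = bootstrap_supports(spec, n_boot=50, seed=9)
        assert a.supports == b.supports

    def test_invalid_n_boot(self):
        spec = self._clade_spectrum()
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_supports(spec, n_boot=0)


class TestTreeModel:
    def test_fit_cohort_newick_and_summary(self, cohort96):
        result = PopulationTree(cohort96).fit(n_boot=50, seed=2)
        nwk = result.newick()
        assert nwk.endswith(";")
        for pop, _, _ in __import__("retropop.synthetic", fromlist=["DEFAULT_POPULATIONS"]).DEFAULT_POPULATIONS:
            assert pop in nwk
        assert "bootstrap replicates: 50" in result.summary()

    def test_structured_cohort_recovers_subspecies_clade(self):
        """With hierarchical (subspecies -> population) structure, confident
        splits exist and every confident split respects subspecies."""
        cfg = SimConfig(seed=31, n_markers=800, fst=0.05, fst_subspecies=0.25)
        pm = simulate_cohort(cfg)
        result = PopulationTree(pm).fit(n_boot=100, seed=3)
        sub_of = {pop: sub for pop, sub, _ in cfg.populations}
        confident = result.high_confidence_splits()
        assert confident, "no split reached 80% support"
        by_sub = {
            s: frozenset(p for p, sub, _ in cfg.populations if sub == s)
            for s in {"domesticus", "musculus", "castaneus"}
        }
        # at least one confident split isolates a whole subspecies
        assert any(s in by_sub.values() for s in confident)
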