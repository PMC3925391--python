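"""Phylogenetic beta diversity: tree building, UniFrac, PCoA, UPGMA."""

import io

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from otupipe.beta import (alignment_distance, build_tree, pcoa,
                          representative_distance_matrix, unifrac_matrix,
                          unweighted_unifrac, upgma_dendrogram,
                          weighted_unifrac)


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def _random_tree(rng, n_leaves):
    """Random rooted binary tree with uniform(0.05, 1) branch lengths."""
    names = [f"L{i}" for i in range(n_leaves)]

    def grow(leaves):
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.uniform(0.05, 1.0):.4f}"
        k = int(rng.integers(1, len(leaves)))
        left, right = leaves[:k], leaves[k:]
        return (f"({grow(left)},{grow(right)}):"
                f"{rng.uniform(0.05, 1.0):.4f}")
    k = max(1, int(rng.integers(1, n_leaves)))
    nwk = f"({grow(names[:k])},{grow(names[k:])});"
    return _tree(nwk), names


# --- brute-force oracle: explicit per-branch leaf sums ----------------------

def oracle_weighted_unifrac(tree, pa, pb, taxa, normalized=True):
    prop_a = dict(zip(taxa, np.asarray(pa, float) / np.sum(pa)))
    prop_b = dict(zip(taxa, np.asarray(pb, float) / np.sum(pb)))
    raw = 0.0
    for node in tree.traverse(include_self=False):
        leaves = [node.name] if node.is_tip() else \
            [t.name for t in node.tips()]
        wa = sum(prop_a.get(n, 0.0) for n in leaves)
        wb = sum(prop_b.get(n, 0.0) for n in leaves)
        raw += (node.length or 0.0) * abs(wa - wb)
    if not normalized:
        return raw
    denom = 0.0
    for tip in tree.tips():
        depth, node = 0.0, tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        denom += depth * (prop_a.get(tip.name, 0.0)
                          + prop_b.get(tip.name, 0.0))
    return raw / denom if denom else 0.0


class TestBuildTree:
    def test_three_taxon_distances_are_additive(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 300))

        def mutate(seq, n, seed):
            r = np.random.default_rng(seed)
            s = list(seq)
            for p in r.choice(len(s), n, replace=False):
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            return "".join(s)

        seqs = [("A", base), ("B", mutate(base, 15, 1)),
                ("C", mutate(base, 30, 2))]
        dm = representative_distance_matrix(seqs)
        tree = build_tree(seqs)
        td = tree.tip_tip_distances()
        for x in "ABC":
            for y in "ABC":
                # NJ is exact on 3 taxa (closed-form branch lengths)
                assert td[x, y] == pytest.approx(dm[x, y], abs=1e-9)

    def test_identical_sequences_zero_cherry(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), 200))
        other = "".join(rng.choice(list("ACGT"), 200))
        tree = build_tree([("A", base), ("B", base), ("C", other)])
        assert tree.tip_tip_distances()["A", "B"] == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            representative_distance_matrix([("A", "ACGT"), ("A", "ACGT")])

    def test_congeneric_species_form_clades(self, small_run):
        """>= 90% of multi-OTU genera are monophyletic in the OTU tree."""
        _, result, _ = small_run
        reps = [(o.otu_id, o.representative.sequence) for o in result.otus]
        tree = build_tree(reps)
        genus_of = result.otu_table.taxonomy["genus"]
        genera = genus_of[genus_of != ""].groupby(genus_of).groups
        multi = {g: list(ids) for g, ids in genera.items() if len(ids) >= 2}
        assert multi
        mono = 0
        for g, otu_ids in multi.items():
            lca = tree.lowest_common_ancestor(otu_ids)
            below = {t.name for t in lca.tips()}
            mono += below == set(otu_ids)
        assert mono / len(multi) >= 0.9


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        tree = _tree("(L1:1,L2:1);")
        assert weighted_unifrac(tree, [3, 1], [3, 1], ["L1", "L2"]) == 0.0

    def test_star_disjoint_is_one(self):
        tree = _tree("(L1:1,L2:1);")
        assert weighted_unifrac(tree, [1, 0], [0, 1], ["L1", "L2"]) \
            == pytest.approx(1.0)
        raw = weighted_unifrac(tree, [1, 0], [0, 1], ["L1", "L2"],
                               normalized=False)
        assert raw == pytest.approx(2.0)

    def test_star_half_overlap(self):
        tree = _tree("(L1:1,L2:1);")
        d = weighted_unifrac(tree, [0.5, 0.5], [1, 0], ["L1", "L2"])
        assert d == pytest.approx(0.5)
        raw = weighted_unifrac(tree, [0.5, 0.5], [1, 0], ["L1", "L2"],
                               normalized=False)
        assert raw == pytest.approx(1.0)

    def test_matches_bruteforce_on_small_trees(self):
        """Branch traversal equals the explicit leaf-sum oracle on random
        trees with <= 8 leaves, 100 proportion pairs."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            tree, names = _random_tree(rng, int(rng.integers(2, 9)))
            pa = rng.dirichlet(np.ones(len(names)))
            pb = rng.dirichlet(np.ones(len(names)))
            for normalized in (True, False):
                mine = weighted_unifrac(tree, pa, pb, names,
                                        normalized=normalized)
                oracle = oracle_weighted_unifrac(tree, pa, pb, names,
                                                 normalized=normalized)
                assert mine == pytest.approx(oracle, abs=1e-12)
            checked += 1

    def test_matches_skbio(self):
        from skbio.diversity.beta import weighted_unifrac as sk_wu

        rng = np.random.default_rng(8)
        for _ in range(20):
            tree, names = _random_tree(rng, 6)
            ca = rng.integers(0, 50, len(names))
            cb = rng.integers(0, 50, len(names))
            if ca.sum() == 0 or cb.sum() == 0:
                continue
            mine = weighted_unifrac(tree, ca, cb, names, normalized=True)
            ref = sk_wu(ca, cb, names, tree.copy(), normalized=True)
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_scaling_invariance_and_symmetry(self):
        rng = np.random.default_rng(9)
        tree, names = _random_tree(rng, 7)
        ca = rng.integers(1, 40, len(names))
        cb = rng.integers(1, 40, len(names))
        d1 = weighted_unifrac(tree, ca, cb, names)
        assert weighted_unifrac(tree, ca * 17, cb, names) \
            == pytest.approx(d1, abs=1e-12)
        assert weighted_unifrac(tree, cb, ca, names) \
            == pytest.approx(d1, abs=1e-12)

    def test_missing_leaf_errors(self):
        tree = _tree("(L1:1,L2:1);")
        with pytest.raises(ValueError, match="missing"):
            weighted_unifrac(tree, [1, 0, 0], [0, 1, 0], ["L1", "L2", "L9"])


class TestUnweightedUnifrac:
    def test_hand_cases(self):
        tree = _tree("(L1:1,L2:1);")
        assert unweighted_unifrac(tree, [2, 1], [5, 9], ["L1", "L2"]) == 0.0
        assert unweighted_unifrac(tree, [1, 0], [0, 1], ["L1", "L2"]) == 1.0
        assert unweighted_unifrac(tree, [1, 1], [1, 0], ["L1", "L2"]) \
            == pytest.approx(0.5)

    def test_matches_skbio(self):
        from skbio.diversity.beta import unweighted_unifrac as sk_uu

        rng = np.random.default_rng(10)
        for _ in range(20):
            tree, names = _random_tree(rng, 6)
            ca = rng.integers(0, 2, len(names)) * rng.integers(1, 30)
            cb = rng.integers(0, 2, len(names)) * rng.integers(1, 30)
            if ca.sum() == 0 or cb.sum() == 0:
                continue
            mine = unweighted_unifrac(tree, ca, cb, names)
            assert mine == pytest.approx(
                sk_uu(ca, cb, names, tree.copy()), abs=1e-10)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(11)
        tree, names = _random_tree(rng, 8)
        samples = [(rng.integers(0, 2, len(names)) * rng.integers(1, 9))
                   for _ in range(8)]
        samples = [s for s in samples if s.sum() > 0]
        for a in samples:
            for b in samples:
                for c in samples:
                    dab = unweighted_unifrac(tree, a, b, names)
                    dbc = unweighted_unifrac(tree, b, c, names)
                    dac = unweighted_unifrac(tree, a, c, names)
                    assert dac <= dab + dbc + 1e-12


class TestPCoA:
    def test_two_point_closed_form(self):
        d = 0.8
        res = pcoa(np.array([[0, d], [d, 0]]), axes=3)
        assert res.eigenvalues[0] == pytest.approx(d * d / 2, abs=1e-12)
        coords = res.coordinates.iloc[:, 0].to_numpy()
        assert sorted(coords) == pytest.approx([-d / 2, d / 2], abs=1e-12)

    def test_planar_round_trip(self):
        """Euclidean distances of planar points are re-embedded exactly up
        to rotation/reflection (Procrustes residual < 1e-8)."""
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(20, 2))
        dm = squareform(pdist(pts))
        res = pcoa(dm, axes=2)
        x = res.coordinates.to_numpy()
        x0 = x - x.mean(axis=0)
        p0 = pts - pts.mean(axis=0)
        rot, _ = orthogonal_procrustes(x0, p0)
        assert np.linalg.norm(x0 @ rot - p0) < 1e-8

    def test_zero_matrix_and_asymmetry(self):
        res = pcoa(np.zeros((4, 4)))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0, 1], [2, 0]], dtype=float))

    def test_matches_skbio_embedding(self, small_run):
        """Eigenvalues and coordinates (up to sign) agree with scikit-bio's
        PCoA. Variance fractions are not compared: this implementation
        normalizes by the positive eigenvalue sum, skbio by the full sum."""
        from skbio.stats.ordination import pcoa as sk_pcoa

        _, result, _ = small_run
        dm = result.unifrac_weighted
        res = pcoa(dm, axes=3)
        ref = sk_pcoa(dm, dimensions=3)
        assert res.eigenvalues[:3] == pytest.approx(
            ref.eigvals.to_numpy()[:3], abs=1e-9)
        for i in range(3):
            mine = res.coordinates.iloc[:, i].to_numpy()
            theirs = ref.samples.iloc[:, i].to_numpy()
            assert min(np.abs(mine - theirs).max(),
                       np.abs(mine + theirs).max()) < 1e-8


class TestUPGMA:
    def test_closest_pair_merges_first(self):
        dm = DistanceMatrix(np.array([[0, 0.1, 0.9], [0.1, 0, 0.9],
                                      [0.9, 0.9, 0]]), ["A", "B", "C"])
        nwk, z = upgma_dendrogram(dm)
        assert "(A:0.05,B:0.05)" in nwk
        assert (np.diff(z[:, 2]) >= -1e-12).all()  # non-decreasing heights

    def test_ultrametric_input_recovered_exactly(self):
        """Cophenetic distances of the UPGMA tree reproduce an ultrametric
        input matrix."""
        rng = np.random.default_rng(13)
        tree, names = _random_tree(rng, 6)
        # make ultrametric: set distances to max depth of merge height
        z0 = hierarchy.linkage(rng.random(15), method="average")
        d = squareform(hierarchy.cophenet(z0))
        dm = DistanceMatrix(d, [f"L{i}" for i in range(6)])
        _, z = upgma_dendrogram(dm)
        assert np.allclose(squareform(hierarchy.cophenet(z)), d, atol=1e-10)


class TestGroupSeparation:
    def test_between_exceeds_within(self, small_run):
        """Distinct HC vs IBD profiles push between-group weighted UniFrac
        above within-group distances (one-sided Welch p < 0.01)."""
        from scipy import stats as sps

        from otupipe.beta import distance_long_table

        _, result, _ = small_run
        long = distance_long_table(result.unifrac_weighted, result.groups)
        hc_mask = (long.group_a == "HC") ^ (long.group_b == "HC")
        within_hc = long[(long.group_a == "HC") & (long.group_b == "HC")]
        between = long[hc_mask]
        res = sps.ttest_ind(between.distance, within_hc.distance,
                            equal_var=False, alternative="greater")
        assert res.pvalue < 0.01
        assert between.distance.mean() > within_hc.distance.mean()


def test_unifrac_matrix_consistent_with_pairwise(small_run):
    _, result, _ = small_run
    table = result.otu_table
    reps = [(o.otu_id, o.representative.sequence) for o in result.otus]
    tree = build_tree(reps)
    dm = unifrac_matrix(tree, table.counts, "weighted")
    s1, s2 = table.counts.columns[0], table.counts.columns[5]
    direct = weighted_unifrac(tree, table.counts[s1], table.counts[s2],
                              list(table.counts.index))
    assert dm[s1, s2] == pytest.approx(direct, abs=1e-12)


def test_alignment_distance_basics():
    assert alignment_distance("ACGT", "ACGT") == 0.0
    assert alignment_distance("ACGT", "ACGA") == pytest.approx(0.25)
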