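"""Distances, neighbor joining, and the Z/W cluster test."""

import itertools

import numpy as np
import pytest

from sexscan.phylo import (
    ClusterVerdict,
    DistanceMatrix,
    bipartitions,
    gametolog_cluster_test,
    nj_build,
    pairwise_distance,
)
from sexscan.simulate import SeqSet, simulate_gametologs


class TestDistances:
    def test_identical_sequences_zero(self):
        s = "ACGT" * 10
        assert pairwise_distance(s, s, "p") == 0.0
        assert pairwise_distance(s, s, "k2p") == 0.0

    def test_p_distance_simple(self):
        a, b = "ACGT" * 5, ("ACGT" * 5)[:-1] + "A"
        assert pairwise_distance(a, b, "p") == pytest.approx(1 / 20)

    def test_k2p_formula_instance(self):
        # 100 sites, 10 transitions (A<->G), 5 transversions (A<->C)
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        d = pairwise_distance(a, b, "k2p")
        expected = -0.5 * np.log(1 - 2 * 0.1 - 0.05) - 0.25 * np.log(1 - 2 * 0.05)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(0.17018, abs=5e-6)

    def test_saturation_is_an_error(self):
        a = "A" * 40
        b = "G" * 40  # all transitions: 1 - 2P - Q <= 0
        with pytest.raises(ValueError, match="saturated"):
            pairwise_distance(a, b, "k2p")

    def test_end_trimming_and_min_sites(self):
        a, b = "ACGT" * 10, "ACGT" * 5
        assert pairwise_distance(a, b, "p") == 0.0  # trimmed to 20 shared sites
        with pytest.raises(ValueError, match="comparable sites"):
            pairwise_distance("ACGT", "ACGT", "p")


def _tree_distances(newick_like: dict, labels) -> np.ndarray:
    """Path-length matrix from {label: {label: d}} helper."""
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = newick_like[frozenset((a, b))]
    return d


def _random_additive(rng, n):
    """Random binary tree -> (path-length matrix, set of nontrivial splits)."""
    nodes = [(str(i), frozenset([str(i)])) for i in range(n)]
    children: dict = {}
    lengths: dict = {}
    counter = itertools.count(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (a, sa), (b, sb) = nodes[i], nodes[j]
        parent = str(next(counter))
        children[parent] = [a, b]
        lengths[a] = rng.uniform(0.1, 1.0)
        lengths[b] = rng.uniform(0.1, 1.0)
        nodes = [nodes[x] for x in range(len(nodes)) if x not in (i, j)]
        nodes.append((parent, sa | sb))
    root = nodes[0][0]

    leaf_paths = {}

    def walk(node, path):
        if node not in children:
            leaf_paths[node] = path
            return
        for ch in children[node]:
            walk(ch, path + [(ch, lengths[ch])])

    walk(root, [])
    labels = sorted(leaf_paths, key=int)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                ea = dict(leaf_paths[a])
                eb = dict(leaf_paths[b])
                shared = set(ea) & set(eb)
                dist = (sum(ea.values()) + sum(eb.values())
                        - 2 * sum(ea[e] for e in shared))
                d[i, j] = d[j, i] = dist
    splits = set()
    all_leaves = frozenset(labels)
    for node, kids in children.items():
        pass
    # recompute tip sets per internal edge
    tipsets: dict = {}

    def tips_below(node):
        if node not in children:
            return frozenset([node])
        s = frozenset()
        for ch in children[node]:
            s |= tips_below(ch)
        tipsets[node] = s
        return s

    tips_below(root)
    for node, s in tipsets.items():
        if node != root and 1 < len(s) < n - 1:
            splits.add(min(s, all_leaves - s, key=sorted))
    return labels, d, splits


def _nj_splits(tree, n):
    return {min(s, frozenset(t.name for t in tree.tips()) - s, key=sorted)
            for s in bipartitions(tree)}


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        """Distances from ((A:1,B:2):1.5,C:3,D:4) are reproduced exactly."""
        labels = list("ABCD")
        d = np.array([[0.0, 3.0, 5.5, 6.5],
                      [3.0, 0.0, 6.5, 7.5],
                      [5.5, 6.5, 0.0, 7.0],
                      [6.5, 7.5, 7.0, 0.0]])
        tree = nj_build(DistanceMatrix(labels, d))
        td = tree.tip_tip_distances()
        ids = list(td.ids)
        expect = DistanceMatrix(labels, d)
        perm = [labels.index(x) for x in ids]
        assert np.allclose(td.data, d[np.ix_(perm, perm)], atol=1e-9)
        assert frozenset("AB") in _nj_splits(tree, 4) or frozenset("CD") in _nj_splits(tree, 4)

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_build(DistanceMatrix(list("ABC"), d))
        lens = {t.name: t.length for t in tree.tips()}
        assert lens["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lens["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lens["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("seed", range(20))
    def test_additive_recovery(self, seed):
        """Random additive matrices (4-12 taxa): topology and path lengths
        recovered exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels, d, true_splits = _random_additive(rng, n)
        tree = nj_build(DistanceMatrix(labels, d))
        td = tree.tip_tip_distances()
        perm = [labels.index(x) for x in td.ids]
        assert np.allclose(td.data, d[np.ix_(perm, perm)], atol=1e-9)
        assert _nj_splits(tree, n) == true_splits

    def test_matches_skbio_reference(self):
        """Cross-check against the scikit-bio NJ implementation."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(3)
        labels, d, _ = _random_additive(rng, 8)
        mine = nj_build(DistanceMatrix(labels, d))
        theirs = sk_nj(SkDM(d, ids=labels))
        assert mine.compare_rfd(theirs) == 0.0

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(9)
        labels, d, _ = _random_additive(rng, 7)
        perm = list(rng.permutation(len(labels)))
        t1 = nj_build(DistanceMatrix(labels, d))
        t2 = nj_build(DistanceMatrix([labels[i] for i in perm],
                                     d[np.ix_(perm, perm)]))
        assert t1.compare_rfd(t2) == 0.0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("AB"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_negative_branch_clamped_with_warning(self):
        # three-point formula gives a negative terminal branch for A
        d = np.array([[0.0, 0.2, 0.2], [0.2, 0.0, 0.5], [0.2, 0.5, 0.0]])
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_build(DistanceMatrix(list("ABC"), d))
        assert all((t.length or 0) >= 0 for t in tree.traverse())


class TestClusterTest:
    def _tree(self, d, labels):
        return nj_build(DistanceMatrix(labels, np.asarray(d, dtype=float)))

    def test_gametolog_clustered_topology(self):
        labels = ["Emu_W", "Ear_W", "Lag_Z", "Ear_Z"]
        d = [[0.0, 0.1, 0.8, 0.8],
             [0.1, 0.0, 0.8, 0.8],
             [0.8, 0.8, 0.0, 0.1],
             [0.8, 0.8, 0.1, 0.0]]
        classes = {"Emu_W": "W", "Ear_W": "W", "Lag_Z": "Z", "Ear_Z": "Z"}
        assert gametolog_cluster_test(self._tree(d, labels), classes) \
            is ClusterVerdict.BY_GAMETOLOG

    def test_species_clustered_topology(self):
        labels = ["Emu_W", "Emu_Z", "Ear_W", "Ear_Z"]
        d = [[0.0, 0.1, 0.8, 0.8],
             [0.1, 0.0, 0.8, 0.8],
             [0.8, 0.8, 0.0, 0.1],
             [0.8, 0.8, 0.1, 0.0]]
        classes = {"Emu_W": "W", "Ear_W": "W", "Emu_Z": "Z", "Ear_Z": "Z"}
        assert gametolog_cluster_test(self._tree(d, labels), classes) \
            is ClusterVerdict.BY_SPECIES

    def test_mixed_topology(self):
        labels = ["A_W", "A_Z", "B_W", "B_Z", "C_W", "C_Z"]
        # A clusters by species, B/C cluster by gametolog: neither verdict
        d = np.full((6, 6), 0.8)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.05  # A_W with A_Z
        d[2, 4] = d[4, 2] = 0.05  # B_W with C_W
        d[3, 5] = d[5, 3] = 0.05  # B_Z with C_Z
        classes = {lab: lab[-1] for lab in labels}
        assert gametolog_cluster_test(self._tree(d, labels), classes) \
            is ClusterVerdict.MIXED

    def test_missing_class_rejected(self):
        labels = ["A_W", "A_Z", "B_W", "B_Z"]
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        tree = self._tree(d, labels)
        with pytest.raises(ValueError, match="class missing"):
            gametolog_cluster_test(tree, {"A_W": "W"})

    def test_exhaustive_quartets_and_quintets(self):
        """Whenever the ZW split edge exists, the verdict is by_gametolog:
        checked on every labeled quartet/quintet topology."""
        import itertools as it

        for n_w in (2, 3):
            labels = [f"s{i}_W" for i in range(n_w)] + ["x_Z", "y_Z"]
            classes = {lab: lab[-1] for lab in labels}
            for perm in it.permutations(labels):
                d = np.zeros((len(labels), len(labels)))
                for i, a in enumerate(perm):
                    for j, b in enumerate(perm):
                        if i == j:
                            continue
                        same = classes[a] == classes[b]
                        d[labels.index(a), labels.index(b)] = 0.1 if same else 1.0
                tree = self._tree(d, labels)
                assert gametolog_cluster_test(tree, classes) \
                    is ClusterVerdict.BY_GAMETOLOG


class TestGametologSimulation:
    def test_suppression_first_history_clusters_by_gametolog(self):
        seqset = simulate_gametologs(4, seed=7)
        tree = nj_build(DistanceMatrix.from_seqset(seqset))
        assert gametolog_cluster_test(tree, seqset.classes) \
            is ClusterVerdict.BY_GAMETOLOG

    def test_precondition_enforced(self):
        with pytest.raises(ValueError, match="t_zw_split"):
            simulate_gametologs(4, t_zw_split=0.0, seed=1)

    def test_no_zw_divergence_rarely_clusters_by_gametolog(self):
        """With t_zw_split=0 the gametolog edge has length zero, so NJ
        resolves it by noise: the by_gametolog rate over seeds stays low."""
        hits = 0
        for seed in range(20):
            seqset = simulate_gametologs(4, t_zw_split=0.0, seed=seed,
                                         enforce_history=False)
            tree = nj_build(DistanceMatrix.from_seqset(seqset, "p"))
            if gametolog_cluster_test(tree, seqset.classes) \
                    is ClusterVerdict.BY_GAMETOLOG:
                hits += 1
        assert hits <= 10

    def test_mean_divergence_matches_jc_expectation(self):
        """Mean p-distance between Z and W copies of one species matches the
        Jukes-Cantor expectation at the simulated divergence."""
        t_zw, depth = 0.15, 0.05
        dists, total_t = [], []
        for seed in range(30):
            seqset = simulate_gametologs(3, t_zw_split=t_zw,
                                         t_speciation_max=depth, seed=seed)
            seqs = {label: (seq, cls) for label, seq, cls in seqset.records}
            for sp in {label.rsplit("_", 1)[0] for label in seqs}:
                z, w = seqs[f"{sp}_Z"][0], seqs[f"{sp}_W"][0]
                dists.append(pairwise_distance(z, w, "p"))
        # Z_i and W_i share only the gametolog root: path 2*t_zw + 2*depth_i,
        # depth_i ~ U(0.5, 1)*depth in expectation 0.75*depth
        t_exp = 2 * t_zw + 2 * 0.75 * depth
        p_exp = 0.75 * (1 - np.exp(-4 * t_exp / 3))
        assert np.mean(dists) == pytest.approx(p_exp, abs=0.02)
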