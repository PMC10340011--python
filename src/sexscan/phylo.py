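"""Gametolog gene genealogies: pairwise distances, neighbor-joining, and the
Z-vs-W clustering test.

If recombination between Z and W stopped before the sampled species diverged,
the W-borne copies of a locus across species are closer to each other than to
their own species' Z copy, and an unrooted gene tree contains an edge that
bipartitions the tips exactly into the Z set and the W set. The cluster test
checks for that edge; the contrasting outcome is species-wise monophyly.

Distances use either the raw mismatch proportion (p) or the Kimura
two-parameter model, d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q), with P and Q the
transition and transversion fractions. Sequences are assumed pre-aligned and
gapless (SNP-only tag model); unequal lengths are end-trimmed to the shared
window. Neighbor joining follows Saitou & Nei with the standard Q-criterion
and branch-length formulas; ties pick the lexicographically smallest label
pair and negative length estimates are clamped to zero (flagged).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

_PURINES = frozenset("AG")


class DistanceModel(str, enum.Enum):
    P = "p"
    K2P = "k2p"


def pairwise_distance(a: str, b: str, model: DistanceModel | str = DistanceModel.K2P,
                      min_sites: int = 20) -> float:
    """Distance between two pre-aligned sequences after end-trimming."""
    model = DistanceModel(model)
    n = min(len(a), len(b))
    if n < min_sites:
        raise ValueError(f"only {n} comparable sites (< {min_sites})")
    a, b = a[:n].upper(), b[:n].upper()
    transitions = transversions = 0
    for x, y in zip(a, b):
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if model is DistanceModel.P:
        return (transitions + transversions) / n
    P, Q = transitions / n, transversions / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distance undefined (saturated)")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(self.data).all():
            raise ValueError("distance matrix has non-finite entries")
        if (self.data < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")

    @classmethod
    def from_seqset(cls, seqset, model: DistanceModel | str = DistanceModel.K2P,
                    min_sites: int = 20) -> "DistanceMatrix":
        labels = [label for label, _, _ in seqset.records]
        seqs = [seq for _, seq, _ in seqset.records]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pairwise_distance(seqs[i], seqs[j], model,
                                                      min_sites)
        return cls(labels, d)


def nj_build(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating
    root, internal degree 3)."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes = [TreeNode(name=label) for label in dm.labels]
    # deterministic tie-break key: the smallest tip label under each subtree
    keys = list(dm.labels)
    d = dm.data.astype(float).copy()
    clamped = False

    if n == 2:
        root = TreeNode()
        for node in nodes:
            node.length = d[0, 1] / 2.0
            root.append(node)
        return root

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        pairs = [(i, j) for i in range(m) for j in range(i + 1, m)
                 if q[i, j] <= qmin + 1e-12]
        i, j = min(pairs, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d2[-1, -1] = 0.0
        d = d2
        new_key = min(keys[i], keys[j])
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [new_key]

    # resolve the final three around an unrooted center (3-point formulas)
    root = TreeNode()
    (a, b, c) = range(3)
    lens = (
        0.5 * (d[a, b] + d[a, c] - d[b, c]),
        0.5 * (d[a, b] + d[b, c] - d[a, c]),
        0.5 * (d[a, c] + d[b, c] - d[a, b]),
    )
    for node, ln in zip(nodes, lens):
        if ln < 0:
            clamped = True
        node.length = max(ln, 0.0)
        root.append(node)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    return root


def tree_tip_distances(tree: TreeNode) -> DistanceMatrix:
    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    return DistanceMatrix(labels, dm.data)


def bipartitions(tree: TreeNode) -> list[frozenset]:
    """Tip-set sides of every internal edge of the unrooted tree."""
    out = []
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            out.append(side)
    return out


class ClusterVerdict(str, enum.Enum):
    BY_GAMETOLOG = "by_gametolog"
    BY_SPECIES = "by_species"
    MIXED = "mixed"


def gametolog_cluster_test(tree: TreeNode, classes: dict[str, str]
                           ) -> ClusterVerdict:
    """Does the unrooted tree split Z from W, or group by species instead?

    Tip labels are expected as ``<species>_<class>``; ``classes`` maps each
    label to "Z" or "W".
    """
    tips = [t.name for t in tree.tips()]
    missing = [t for t in tips if t not in classes]
    if missing:
        raise ValueError(f"class missing for tip(s): {missing}")
    z_set = frozenset(t for t in tips if classes[t] == "Z")
    w_set = frozenset(t for t in tips if classes[t] == "W")
    if len(z_set) < 2 or len(w_set) < 2:
        raise ValueError("need >= 2 tips per gametolog class")

    splits = set(bipartitions(tree))
    if z_set in splits or w_set in splits:
        return ClusterVerdict.BY_GAMETOLOG

    species: dict[str, set] = {}
    for t in tips:
        species.setdefault(t.rsplit("_", 1)[0], set()).add(t)
    all_tips = frozenset(tips)
    by_species = all(
        len(group) == 1 or frozenset(group) in splits
        or all_tips - frozenset(group) in splits
        for group in species.values()
    )
    return ClusterVerdict.BY_SPECIES if by_species else ClusterVerdict.MIXED
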