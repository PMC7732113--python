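"""Neighbour-joining with locus bootstrap, clone assignment, and PCoA.

Clone detection follows the standard practice for clonal plants: build a
pairwise genetic distance matrix, then call groups of ramets as the
single-linkage connected components under a mismatch threshold (default
0.2 on the Bruvo scale), so any chain of pairwise-similar samples collapses
into one clonal lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import skbio
from scipy.linalg import eigh

from .distances import bruvo_distance_matrix
from .model import DistanceMatrix, GenotypeMatrix

__all__ = [
    "neighbor_joining",
    "tree_bipartitions",
    "bootstrap_support",
    "majority_rule_consensus",
    "CloneAssignment",
    "assign_clones",
    "PCoAResult",
    "pcoa",
]


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> skbio.TreeNode:
    """Saitou-Nei neighbour joining on the Q-criterion.

    Ties in the Q-criterion are broken by the smallest (i, j) index pair in
    the current agglomeration order; negative branch lengths are clamped to
    zero with the deficit transferred to the sister edge, preserving the
    path length between the joined pair.  Returns an unrooted tree
    represented with a trifurcating root.
    """
    n = len(dm)
    if n < 3:
        raise ValueError(f"neighbour joining needs >= 3 taxa, got {n}")
    nodes = [skbio.TreeNode(name=s) for s in dm.ids]
    D = dm.d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, 1)
        k = int(np.argmin(q[iu]))  # first occurrence = smallest (i, j) pair
        bi, bj = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = D[bi, bj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        a, b = nodes[bi], nodes[bj]
        a.length, b.length = float(li), float(max(lj, 0.0))
        new = skbio.TreeNode(children=[a, b])
        d_new = 0.5 * (D[bi, :] + D[bj, :] - D[bi, bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        D = np.vstack([D[np.ix_(keep, keep)], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        np.maximum(D, 0.0, out=D)
        nodes = [nodes[k] for k in keep] + [new]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        node.length = float(max(length, 0.0))
    return skbio.TreeNode(children=list(nodes))


def tree_bipartitions(tree: skbio.TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    lexicographically smaller leaf-name side."""
    leaves = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def bootstrap_support(
    genotypes: GenotypeMatrix,
    metric: Callable[[GenotypeMatrix, Sequence[str] | None], DistanceMatrix] = bruvo_distance_matrix,
    n_boot: int = 1000,
    seed: int | None = None,
) -> skbio.TreeNode:
    """NJ tree on the full data with locus-bootstrap support percentages.

    Loci (columns) are resampled with replacement ``n_boot`` times; the
    support of each internal edge of the full-data tree is the percentage of
    replicate trees containing the same bipartition, stored both as
    ``node.support`` and as the internal node name (so Newick export carries
    it).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(genotypes.loci) < 2:
        raise ValueError("locus bootstrap needs >= 2 loci")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(metric(genotypes, None))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree_bipartitions(full)}
    loci = genotypes.loci
    for _ in range(n_boot):
        resampled = [loci[k] for k in rng.integers(0, len(loci), size=len(loci))]
        rep = neighbor_joining(metric(genotypes, resampled))
        for bp in tree_bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    leaves = frozenset(t.name for t in full.tips())
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        pct = 100.0 * counts[key] / n_boot
        node.support = pct
        node.name = str(int(round(pct)))
    return full


def majority_rule_consensus(trees: Sequence[skbio.TreeNode]) -> skbio.TreeNode:
    """Majority-rule consensus of bootstrap replicate trees (parity output;
    supports are reported on the full-data tree by default)."""
    result = skbio.tree.majority_rule([t.copy() for t in trees])
    return result[0] if isinstance(result, (list, tuple)) else result


# ---------------------------------------------------------------------------
# clone assignment
# ---------------------------------------------------------------------------

@dataclass
class CloneAssignment:
    """Partition of samples into clonal groups.

    ``group_of`` maps each sample to its group label; groups are the
    single-linkage connected components at the mismatch threshold.
    """

    group_of: dict[str, str]
    threshold: float = 0.2
    linkage: str = "single"

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.group_of.items():
            out.setdefault(g, []).append(s)
        return out

    def labels(self, order: Sequence[str]) -> list[str]:
        return [self.group_of[s] for s in order]


def assign_clones(dm: DistanceMatrix, threshold: float = 0.2) -> CloneAssignment:
    """Group samples whose pairwise distance chains below ``threshold``.

    Single-linkage transitive closure: two samples share a clone group if
    they are connected by any path of pairwise distances <= threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    n = len(dm)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dm.d[i, j] <= threshold:
                parent[find(i)] = find(j)
    roots: dict[int, str] = {}
    group_of: dict[str, str] = {}
    for i, s in enumerate(dm.ids):
        root = find(i)
        if root not in roots:
            roots[root] = f"clone_{len(roots) + 1}"
        group_of[s] = roots[root]
    return CloneAssignment(group_of, threshold)


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    ids: list[str]
    coordinates: np.ndarray  # n x k, axes in decreasing eigenvalue order
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical metric scaling (Torgerson) of a distance matrix.

    Double-centres ``-0.5 * D**2``, eigendecomposes, and keeps axes with
    positive eigenvalues in decreasing order.  Explained proportions are
    relative to the sum of positive eigenvalues only.
    """
    n = len(dm)
    d2 = dm.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(vals.max(initial=0.0), 1.0)
    if not pos.any():
        return PCoAResult(dm.ids, np.zeros((n, 1)), np.zeros(1), np.ones(1))
    vals, vecs = vals[pos], vecs[:, pos]
    coords = vecs * np.sqrt(vals)
    explained = vals / vals.sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        vals = vals[:n_axes]
        explained = explained[:n_axes]
    return PCoAResult(dm.ids, coords, vals, explained)
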