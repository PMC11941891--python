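"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

The tree is built by the Saitou-Nei neighbor-joining algorithm with the
Studier-Keppler Q criterion from pairwise p-distances (fraction of
mismatched sites under pairwise gap deletion; a Poisson correction
-ln(1-p) is available). Support values come from column-resampling
bootstrap replicates; groups are obtained by cutting the longest
internal edges. NJ is consistent: on an additive distance matrix it
recovers the generating tree exactly.

The multiple alignment itself is an external input (any aligner); a
trivial no-gap "aligner" for equal-length sequences is provided for
fixtures only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .seqio import ProteinRecord

GAP = "-"


@dataclass
class Alignment:
    """Equal-length gapped rows; at least 3 sequences for tree building."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must all have the same length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: sample columns with replacement."""
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        mat = np.array([list(r) for r in self.rows])
        return Alignment(list(self.ids), ["".join(row) for row in mat[:, cols]])


def as_alignment(records: Iterable[ProteinRecord]) -> Alignment:
    """Treat equal-length, ungapped sequences as an alignment (fixtures only)."""
    records = list(records)
    if len({len(r.seq) for r in records}) > 1:
        raise ValueError("sequences differ in length; run a real aligner first")
    return Alignment([r.id for r in records], [r.seq for r in records])


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal not zero")
        if not np.isfinite(self.values).all() or (self.values < -1e-12).any():
            raise ValueError("distances must be finite and non-negative")


def p_distance(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances under pairwise gap deletion.

    d(i,j) = mismatches / sites compared, where any column gapped in
    either row is excluded. ``model="poisson"`` applies the Poisson
    multiple-hit correction -ln(1-p). A pair with zero comparable sites
    is an error.
    """
    n = len(alignment.rows)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    mat = np.array([list(r) for r in alignment.rows])
    ungapped = mat != GAP
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ungapped[i] & ungapped[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {alignment.ids[i]} "
                    f"and {alignment.ids[j]}"
                )
            p = float((mat[i, ok] != mat[j, ok]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("p-distance 1.0 cannot be Poisson-corrected")
                p = -math.log(1.0 - p)
            elif model != "p":
                raise ValueError(f"unknown distance model {model!r}")
            D[i, j] = D[j, i] = p
    return DistanceMatrix(list(alignment.ids), D)


@dataclass
class TreeNode:
    """A rooted representation of the (unrooted) NJ tree.

    The root is trifurcating. ``children`` pairs each child with the
    length of the edge above it; ``support`` (internal nodes only) is the
    bootstrap percentage of the bipartition that the edge above this
    node induces.
    """

    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]  # type: ignore[misc]

    def to_newick(self, digits: int = 6) -> str:
        return self._newick(digits) + ";"

    def _newick(self, digits: int) -> str:
        if self.is_leaf:
            return self.label or ""
        inner = ",".join(
            f"{c._newick(digits)}:{_sig(bl, digits)}" for c, bl in self.children
        )
        sup = "" if self.support is None else _sig(self.support, digits)
        return f"({inner}){sup}"


def _sig(x: float, digits: int) -> str:
    if x == 0:
        return "0"
    return f"{x:.{digits}g}"


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Deterministic: Q ties are broken by the lowest (i, j) index pair in
    the current node list (new nodes are appended at the end). Negative
    branch lengths are clamped to zero with the deficit transferred to
    the sister edge, preserving the pair's distance. The returned root
    is trifurcating, so the tree is unrooted.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=i) for i in D.ids]
    d = D.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        best = int(np.argmin(flat))  # row-major upper triangle = lowest (i,j) first
        i, j = int(iu[0][best]), int(iu[1][best])
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d_new

    # join the last three nodes on a trifurcating root
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    return TreeNode(
        children=[
            (nodes[0], max(la, 0.0)),
            (nodes[1], max(lb, 0.0)),
            (nodes[2], max(lc, 0.0)),
        ]
    )


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Leaf bipartitions induced by the internal edges of the unrooted tree.

    Each bipartition is the frozenset of its two leaf-label sides;
    trivial splits (single leaf / all leaves) are excluded.
    """
    all_leaves = frozenset(tree.leaf_labels())
    out: set[frozenset] = set()

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if node is not tree and len(below) > 1 and len(all_leaves - below) > 1:
            out.add(frozenset([below, all_leaves - below]))
        return below

    walk(tree)
    return out


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int | None = None,
    model: str = "p",
) -> TreeNode:
    """NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement ``replicates`` times; each
    replicate is run through p-distance + NJ, and the support of an
    internal edge of the original tree is the percentage of replicates
    whose tree contains the same leaf bipartition. ``replicates=0``
    returns the original tree with supports absent. A fixed seed gives
    bit-identical supports.
    """
    if len(alignment.ids) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    tree = neighbor_joining(p_distance(alignment, model))
    if replicates == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    for _ in range(replicates):
        rep = alignment.resample_columns(rng)
        rep_bps = bipartitions(neighbor_joining(p_distance(rep, model)))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaf_labels())

    def annotate(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(annotate(c) for c, _ in node.children))
        bp = frozenset([below, all_leaves - below])
        if node is not tree and bp in counts:
            node.support = 100.0 * counts[bp] / replicates
        return below

    annotate(tree)
    return tree


def cut_groups(tree: TreeNode, k: int) -> dict[str, int]:
    """Partition leaves into ``k`` groups by removing the longest edges.

    The k-1 longest internal edges are removed (ties broken by traversal
    order); the connected components of what remains are the groups,
    numbered in order of first leaf appearance. If the tree has fewer
    than k-1 internal edges, the longest leaf edges are removed next; in
    that degenerate regime a removed component may carry no leaf, so
    fewer than k leaf groups can result.
    """
    leaves = tree.leaf_labels()
    if not (1 <= k <= len(leaves)):
        raise ValueError("k must be in [1, number of leaves]")

    edges: list[tuple[TreeNode, TreeNode, float, bool]] = []  # parent, child, len, internal

    def walk(node: TreeNode) -> None:
        for c, bl in node.children:
            edges.append((node, c, bl, not c.is_leaf))
            walk(c)

    walk(tree)
    internal = [(i, e) for i, e in enumerate(edges) if e[3]]
    leafed = [(i, e) for i, e in enumerate(edges) if not e[3]]
    ranked = sorted(internal, key=lambda t: (-t[1][2], t[0])) + sorted(
        leafed, key=lambda t: (-t[1][2], t[0])
    )
    cut = {id(e[1]) for _, e in ranked[: k - 1]}  # child nodes whose top edge is cut

    groups: dict[str, int] = {}
    next_group = [0]

    def assign(node: TreeNode, group: int | None) -> None:
        if group is None or id(node) in cut:
            next_group[0] += 1
            group = next_group[0]
        if node.is_leaf:
            groups[node.label] = group  # type: ignore[index]
        for c, _ in node.children:
            assign(c, group)

    assign(tree, None)
    # renumber by first appearance in leaf order
    remap: dict[int, int] = {}
    for leaf in leaves:
        g = groups[leaf]
        if g not in remap:
            remap[g] = len(remap) + 1
    return {leaf: remap[groups[leaf]] for leaf in leaves}
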