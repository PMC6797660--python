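"""Distance-based phylogeny: p/Jukes-Cantor distances, neighbor-joining,
column-bootstrap support, and newick output.

Neighbor-joining follows Saitou & Nei's agglomeration with the standard
Q-criterion; tie-breaks take the first (row-major) minimum, so trees are
deterministic. Negative branch-length estimates are clamped to zero and
flagged. Bootstrap support on an internal edge is the percentage of
column-resampled replicate trees whose NJ tree contains the same bipartition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import SequenceRecord

_IGNORE = set("-N.?")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")


@dataclass
class Clade:
    """Tree node; ``branch_length`` is the edge above this node."""

    name: Optional[str] = None
    branch_length: float = 0.0
    support: Optional[float] = None
    children: list = field(default_factory=list)
    clamped: bool = False  # negative NJ estimate clamped to zero

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: Clade  # unrooted tree stored with a trifurcating root

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized to the side not containing
        the lexicographically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits = set()

        def walk(node: Clade) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        def find(node: Clade, target: str, dist: float) -> Optional[list]:
            """Chain of (node, distance from root) ending at the target leaf."""
            if node.is_leaf:
                return [(node, dist)] if node.name == target else None
            for c in node.children:
                r = find(c, target, dist + c.branch_length)
                if r is not None:
                    return r + [(node, dist)]
            return None

        chain_a = find(self.root, a, 0.0)
        chain_b = find(self.root, b, 0.0)
        if chain_a is None or chain_b is None:
            raise KeyError(f"no path between {a} and {b}")
        dist_a = {id(n): d for n, d in chain_a}
        # first common ancestor walking up from b is the deepest one
        for node, d_b in chain_b:
            if id(node) in dist_a:
                d_lca = dist_a[id(node)]
                return (chain_a[0][1] - d_lca) + (chain_b[0][1] - d_lca)
        raise KeyError(f"no common ancestor for {a} and {b}")


def pairwise_distance(alignment: Sequence[SequenceRecord],
                      model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances under pairwise deletion of gap/N columns.

    p = mismatches / compared sites; JC = -(3/4)·ln(1 - 4p/3).
    """
    if model not in {"p_distance", "jukes_cantor"}:
        raise ValueError(f"unknown model {model!r}")
    if len(alignment) < 2:
        raise ValueError("need at least two aligned sequences")
    lengths = {len(r.seq) for r in alignment}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    labels = [r.id for r in alignment]
    arr = np.array([list(r.seq) for r in alignment])
    valid = ~np.isin(arr, list(_IGNORE))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            sites = int(both.sum())
            if sites == 0:
                raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
            p = float((arr[i][both] != arr[j][both]).sum()) / sites
            if model == "jukes_cantor":
                if p >= 0.75:
                    raise ValueError(
                        f"p={p:.3f} ≥ 0.75 between {labels[i]} and {labels[j]}: "
                        "Jukes-Cantor distance undefined"
                    )
                p = -0.75 * math.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor-joining; deterministic row-major tie-break."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    nodes: list[Clade] = [Clade(name=l) for l in dm.labels]
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major first minimum
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.branch_length, child_i.clamped = max(li, 0.0), li < 0
        child_j.branch_length, child_j.clamped = max(lj, 0.0), lj < 0
        parent = Clade(children=[child_i, child_j])
        # distances from the new node to every other active node
        new_d = np.zeros(d.shape[0] + 1)
        for k_idx, ak in enumerate(active):
            if ak in (ai, aj):
                continue
            new_d[ak] = 0.5 * (d[ai, ak] + d[aj, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d[:-1]
        d[:-1, -1] = new_d[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    # final three nodes join at the unrooted trifurcation
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, l in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.branch_length, node.clamped = max(l, 0.0), l < 0
    return Tree(root=Clade(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_support(alignment: Sequence[SequenceRecord],
                      model: str = "p_distance",
                      n_replicates: int = 1000,
                      seed: int = 0) -> Tree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement; support is the
    percentage of replicate NJ trees containing each bipartition of the
    point-estimate tree. Replicates whose distances are undefined (e.g.
    JC saturation) are skipped.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(pairwise_distance(alignment, model))
    length = len(alignment[0].seq)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    used = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(r.id, "".join(r.seq[c] for c in cols))
            for r in alignment
        ]
        try:
            rep = nj_tree(pairwise_distance(resampled, model))
        except ValueError:
            continue
        used += 1
        rep_bps = rep.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / max(used, 1) for bp, c in counts.items()}
    _annotate_supports(tree, supports)
    return tree


def _annotate_supports(tree: Tree, supports: dict[frozenset, float]) -> None:
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)

    def walk(node: Clade) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            node.support = supports.get(side)
        return below

    walk(tree.root)


def _newick_node(node: Clade) -> str:
    if node.is_leaf:
        if not node.name:
            raise ValueError("unlabeled leaf")
        return f"{node.name}:{node.branch_length:.6g}"
    inner = ",".join(_newick_node(c) for c in node.children)
    label = "" if node.support is None else f"{node.support:g}"
    return f"({inner}){label}:{node.branch_length:.6g}"


def to_newick(tree: Tree) -> str:
    inner = ",".join(_newick_node(c) for c in tree.root.children)
    return f"({inner});"


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
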