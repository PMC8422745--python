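"""Kimura 2-parameter distances and distance-based trees (UPGMA, NJ).

K2P corrects the raw proportions of transitions (P) and transversions (Q)
for multiple hits: d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q). Missing data
is deleted pairwise (each pair uses the sites where both sequences are
called), unlike the complete deletion used for S/pi — the two conventions
match the tools that traditionally produce each table.

Population-level distance is the average between-group K2P distance over
all inter-population sequence pairs; the net version (subtracting the mean
within-population distances) is available via ``net=True``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, Alignment, PopulationMap

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """K2P correction undefined: substitutions are saturated for this pair."""


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance in substitutions per site."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    m = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a in MISSING or b in MISSING:
            continue
        m += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if m == 0:
        raise ValueError("no shared called sites between sequences")
    p, q = ts / m, tv / m
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined for P={p:.4f}, Q={q:.4f} (log argument <= 0)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "population-level"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix entries must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_csv(cls, path, kind: str = "population-level") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        m = df.to_numpy(dtype=float)
        m = np.where(np.isnan(m), 0.0, m)
        m = np.maximum(m, m.T)  # accept lower- or upper-triangular input
        return cls(tuple(str(c) for c in df.columns), m, kind)


def between_population_distance(
    aln: Alignment, pm: PopulationMap, net: bool = False
) -> tuple[DistanceMatrix, dict[str, float]]:
    """Mean inter-population K2P distance matrix and within-population means.

    With ``net=True``, entry(x, y) subtracts the average of the two
    within-population means (Nei's net divergence d_A).
    """
    pm.require_complete(aln)
    pops = pm.populations
    seqs_of = {
        p: [s for sid, s in aln.records if pm.assignments[sid] == p] for p in pops
    }
    for p, seqs in seqs_of.items():
        if not seqs:
            raise ValueError(f"population {p!r} has no sequences")
    within: dict[str, float] = {}
    for p, seqs in seqs_of.items():
        pairs = list(itertools.combinations(seqs, 2))
        within[p] = (
            sum(k2p_distance(a, b) for a, b in pairs) / len(pairs) if pairs else 0.0
        )
    k = len(pops)
    m = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        pairs = list(itertools.product(seqs_of[pops[i]], seqs_of[pops[j]]))
        d = sum(k2p_distance(a, b) for a, b in pairs) / len(pairs)
        if net:
            d -= 0.5 * (within[pops[i]] + within[pops[j]])
        m[i, j] = m[j, i] = max(d, 0.0) if net else d
    return DistanceMatrix(tuple(pops), m), within


# ---------------------------------------------------------------------------
# trees


@dataclass(eq=False)
class TreeNode:
    name: str | None = None
    branch_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: TreeNode
    method: str = ""

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if node.branch_length is not None:
                s += f":{node.branch_length:.10g}"
            return s

        return fmt(self.root) + ";"

    def leaf_distances(self) -> pd.DataFrame:
        """Path-length distances between all leaf pairs."""
        paths: dict[str, dict[TreeNode, float]] = {}

        def walk(node, anc):  # anc: list of (ancestor, distance to node)
            here = [(a, d + (node.branch_length or 0.0)) for a, d in anc] + [(node, 0.0)]
            if node.is_leaf:
                paths[node.name] = dict(here)
            for c in node.children:
                walk(c, here)

        walk(self.root, [])
        names = sorted(paths)
        out = pd.DataFrame(0.0, index=names, columns=names)
        for a, b in itertools.combinations(names, 2):
            shared = set(paths[a]) & set(paths[b])
            d = min(paths[a][x] + paths[b][x] for x in shared)
            out.loc[a, b] = out.loc[b, a] = d
        return out

    def root_to_leaf_depths(self) -> dict[str, float]:
        out = {}

        def walk(node, depth):
            depth += node.branch_length or 0.0
            if node.is_leaf:
                out[node.name] = depth
            for c in node.children:
                walk(c, depth)

        walk(self.root, 0.0)
        return out

    def sibling_group_of(self, name: str) -> set[str]:
        """Leaf names on the other side of the root from the given leaf.

        A leaf 'separated from all others' has every other leaf in this set
        (unrooted interpretation: the leaf is attached by its own edge at
        the deepest split).
        """
        for child in self.root.children:
            sub = _leaf_names_under(child)
            if name in sub and len(sub) == 1:
                return set(self.leaf_names()) - {name}
        return set()


def midpoint_root(tree: Tree) -> Tree:
    """Re-root an (unrooted or arbitrarily rooted) tree at its midpoint.

    The midpoint is the halfway point of the longest leaf-to-leaf path;
    display conventions for NJ trees root there, which is what makes a
    strongly diverged taxon appear 'on its own branch'.
    """
    # collect undirected edges (parent-child, weight = child's branch length)
    adj: dict[int, list[tuple[int, float]]] = {}
    nodes: dict[int, TreeNode] = {}

    def collect(node):
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            w = c.branch_length or 0.0
            adj.setdefault(id(c), [])
            adj[id(node)].append((id(c), w))
            adj[id(c)].append((id(node), w))
            collect(c)

    collect(tree.root)
    leaves = [id(l) for l in tree.leaves()]

    def distances_from(src):
        dist = {src: 0.0}
        prev = {src: None}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    best = (-1.0, None, None)
    d_a = {}
    for a in leaves:
        dist, _ = distances_from(a)
        for b in leaves:
            if dist[b] > best[0]:
                best = (dist[b], a, b)
    diameter, a, b = best
    dist, prev = distances_from(a)
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    path.reverse()  # a ... b
    # find edge along the path containing the midpoint
    half = diameter / 2.0
    acc = 0.0
    u = path[0]
    for v in path[1:]:
        w = next(wt for (x, wt) in adj[u] if x == v)
        if acc + w >= half or v == path[-1]:
            break
        acc += w
        u = v
    x = half - acc  # distance from u into edge (u, v)
    x = min(max(x, 0.0), w)

    # rebuild the tree hanging from a fresh root splitting edge (u, v)
    def hang(node_id, parent_id, length) -> TreeNode:
        old = nodes[node_id]
        new = TreeNode(name=old.name, branch_length=length)
        for nb, wt in adj[node_id]:
            if nb == parent_id:
                continue
            new.children.append(hang(nb, node_id, wt))
        return new

    left = hang(u, v, x)
    right = hang(v, u, w - x)
    root = TreeNode(children=[left, right])
    return Tree(root, method=tree.method + "+midpoint")


def is_isolated_at_root(tree: Tree, name: str) -> bool:
    """True if the named leaf hangs alone from the root (its own branch)."""
    for child in tree.root.children:
        sub = _leaf_names_under(child)
        if sub == {name}:
            return True
    return False


def _leaf_names_under(node: TreeNode) -> set[str]:
    if node.is_leaf:
        return {node.name}
    out: set[str] = set()
    for c in node.children:
        out |= _leaf_names_under(c)
    return out


def upgma(dm: DistanceMatrix) -> Tree:
    """Size-weighted average-linkage clustering; node heights = d/2.

    Ties in the closest pair are broken by the lexicographically smallest
    (label_i, label_j) pair, labels compared as the sorted pair of the
    lexicographically least original labels in each cluster.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    d = {frozenset((i, j)): dm.values[i, j]
         for i, j in itertools.combinations(range(n), 2)}
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=lbl) for i, lbl in enumerate(dm.labels)
    }
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    least = {i: dm.labels[i] for i in range(n)}
    active = set(range(n))
    nxt = n
    while len(active) > 1:
        best = min(
            (
                (d[frozenset((i, j))], tuple(sorted((least[i], least[j]))), i, j)
                for i, j in itertools.combinations(sorted(active), 2)
            ),
        )
        dist, _, i, j = best
        h = dist / 2.0
        for k in (i, j):
            nodes[k].branch_length = h - heights[k]
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[nxt] = parent
        sizes[nxt] = sizes[i] + sizes[j]
        heights[nxt] = h
        least[nxt] = min(least[i], least[j])
        active -= {i, j}
        for k in active:
            d[frozenset((nxt, k))] = (
                sizes[i] * d[frozenset((i, k))] + sizes[j] * d[frozenset((j, k))]
            ) / (sizes[i] + sizes[j])
        active.add(nxt)
        nxt += 1
    (root_id,) = active
    return Tree(nodes[root_id], method="UPGMA")


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard branch-length formulas.

    Negative branch lengths are set to zero and the difference transferred
    to the adjacent branch. Ties in the Q criterion are broken by the
    lexicographically smallest label pair.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 labels")
    ids = list(range(n))
    dist = {frozenset((i, j)): float(dm.values[i, j])
            for i, j in itertools.combinations(ids, 2)}
    nodes = {i: TreeNode(name=lbl) for i, lbl in enumerate(dm.labels)}
    least = {i: dm.labels[i] for i in ids}
    active = list(ids)
    nxt = n
    while len(active) > 2:
        r = len(active)
        totals = {
            i: sum(dist[frozenset((i, k))] for k in active if k != i) for i in active
        }
        best = min(
            (
                (
                    (r - 2) * dist[frozenset((i, j))] - totals[i] - totals[j],
                    tuple(sorted((least[i], least[j]))),
                    i,
                    j,
                )
                for i, j in itertools.combinations(sorted(active), 2)
            ),
        )
        _, _, i, j = best
        dij = dist[frozenset((i, j))]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (r - 2))
        lj = dij - li
        # negative-branch fix: clamp at zero, shift the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[nxt] = parent
        least[nxt] = min(least[i], least[j])
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((nxt, k))] = 0.5 * (
                dist[frozenset((i, k))] + dist[frozenset((j, k))] - dij
            )
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    a, b = active
    dab = dist[frozenset((a, b))]
    # unrooted tree written with a trifurcation when possible; with two
    # remaining nodes, attach b under a's new root with the full distance
    if not nodes[a].is_leaf:
        root = nodes[a]
        nodes[b].branch_length = max(dab, 0.0)
        root.children.append(nodes[b])
    else:
        root = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].branch_length = max(dab, 0.0)
        nodes[b].branch_length = 0.0
    return Tree(root, method="NJ")
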