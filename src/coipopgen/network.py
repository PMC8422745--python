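"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are joined in ascending order of mutational distance up to the
95% parsimony connection limit, keeping every co-minimal alternative
connection (a minimum-spanning network, the variant used by modern
visualization tools). Multi-step edges are subdivided by inferred median
(unsampled) nodes so that every drawn edge represents exactly one mutation.

The connection limit is the largest number of steps j for which the
probability that two haplotypes observed to differ at j of L sites are
separated by exactly j mutations exceeds the chosen confidence. That
probability is computed under a finite-sites Jukes-Cantor multiple-hit
model: successive mutations hit a uniformly chosen site (a hit on an
already-differing site reverts it with probability 1/3), and the true
number of mutations between a random pair carries the pairwise-coalescent
geometric prior with mean equal to the observed difference count, so

    P(parsimony | j) = P(M = j) W(j | j) / sum_{k >= j} P(M = k) W(j | k)

with W(j | k) the k-step transition mass of the difference-count walk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeTable


def _difference_walk_matrix(m: int, max_state: int) -> np.ndarray:
    """One-step transition matrix of the visible-difference count.

    From state x (sites currently differing, out of m): a new mutation hits
    a matching site with probability (m-x)/m (state x+1); hits a differing
    site and reverts it with probability x/(3m) (state x-1); otherwise the
    site stays different (state x).
    """
    s = max_state + 1
    T = np.zeros((s, s))
    for x in range(s):
        up = (m - x) / m if x < max_state else 0.0
        down = x / (3.0 * m)
        T[x, min(x + 1, max_state)] += up
        T[x, max(x - 1, 0)] += down
        T[x, x] += 1.0 - up - down
    return T


def parsimony_probability(j: int, n_sites: int, tail: float = 1e-12) -> float:
    """P(exactly j mutations | j visible differences over n_sites)."""
    if j == 0:
        return 1.0
    if j > n_sites:
        return 0.0
    p_geo = 1.0 / (1.0 + j)  # geometric prior with mean j
    max_state = min(n_sites, 4 * j + 40)
    T = _difference_walk_matrix(n_sites, max_state)
    state = np.zeros(max_state + 1)
    state[0] = 1.0
    num = 0.0
    den = 0.0
    log_surv = 0.0  # running prior tail control
    k = 0
    prior = p_geo
    while True:
        state = state @ T if k > 0 else state
        if k >= 1:
            prior *= 1.0 - p_geo
        if k >= j:
            w = state[j]
            term = prior * w
            den += term
            if k == j:
                num = term
            if prior < tail:
                break
        k += 1
        if k > 100 * j + 1000:  # safety stop
            break
    return num / den if den > 0 else 0.0


def parsimony_connection_limit(n_sites: int, confidence: float = 0.95) -> int:
    """Largest j with parsimony probability exceeding the confidence."""
    if n_sites < 1:
        raise ValueError("need n_sites >= 1")
    if confidence <= 0:
        return n_sites
    limit = 0
    for j in range(1, n_sites + 1):
        if parsimony_probability(j, n_sites) > confidence:
            limit = j
        else:
            break
    return limit


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass(frozen=True)
class HaplotypeNetwork:
    graph: nx.Graph
    connection_limit: int

    @property
    def sampled_nodes(self) -> tuple[str, ...]:
        return tuple(
            n for n, d in self.graph.nodes(data=True) if not d.get("median", False)
        )

    @property
    def median_nodes(self) -> tuple[str, ...]:
        return tuple(
            n for n, d in self.graph.nodes(data=True) if d.get("median", False)
        )


def _median_sequence_path(seq_a: str, seq_b: str) -> list[str]:
    """Intermediate sequences from a to b, flipping differing sites in order."""
    diff_sites = [i for i, (x, y) in enumerate(zip(seq_a, seq_b)) if x != y]
    out = []
    cur = list(seq_a)
    for site in diff_sites[:-1]:
        cur[site] = seq_b[site]
        out.append("".join(cur))
    return out


def build_tcs_network(
    table: HaplotypeTable, limit: int | None = None, confidence: float = 0.95
) -> HaplotypeNetwork:
    """Minimum-spanning network over haplotypes within the parsimony limit.

    Pairs are processed in ascending mutational distance; at each distance
    level every pair joining two still-separate components (as they stood
    before this level) is added, so alternative equally parsimonious
    connections are retained as cycles. Multi-step connections receive
    median nodes (one per intermediate mutation).
    """
    haps = table.haplotypes
    if not haps:
        raise ValueError("empty haplotype table")
    if limit is None:
        limit = parsimony_connection_limit(len(haps[0][1]), confidence)
    g = nx.Graph()
    for hap_id, seq in haps:
        g.add_node(
            hap_id,
            frequency=table.total_count(hap_id),
            sequence=seq,
            median=False,
            populations=dict(table.counts[hap_id]),
        )
    dists = sorted(
        (hamming(a_seq, b_seq), a_id, b_id)
        for (a_id, a_seq), (b_id, b_seq) in itertools.combinations(haps, 2)
    )
    comp = {hap_id: hap_id for hap_id, _ in haps}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    median_count = 0
    for dist, level in itertools.groupby(dists, key=lambda t: t[0]):
        if dist > limit:
            break
        level = list(level)
        before = {h: find(h) for h, _ in haps}
        added = []
        for d, a, b in level:
            if before[a] == before[b]:
                continue  # already connected at a smaller or equal distance
            added.append((a, b, d))
        for a, b, d in added:
            # insert median nodes for multi-step connections
            prev = a
            for mseq in _median_sequence_path(
                g.nodes[a]["sequence"], g.nodes[b]["sequence"]
            ):
                median_count += 1
                mid = f"Median_{median_count}"
                g.add_node(mid, frequency=0, sequence=mseq, median=True,
                           populations={})
                g.add_edge(prev, mid, steps=1)
                prev = mid
            g.add_edge(prev, b, steps=1)
            ra, rb = find(a), find(b)
            comp[ra] = rb
    return HaplotypeNetwork(g, limit)


def central_haplotype(net: HaplotypeNetwork) -> str:
    """Sampled node of maximal frequency.

    Ties go to the node with the smallest eccentricity in its connected
    component (most central), then to the lexicographically least id.
    """
    g = net.graph
    sampled = net.sampled_nodes
    if not sampled:
        raise ValueError("network has no sampled haplotypes")
    max_freq = max(g.nodes[h]["frequency"] for h in sampled)
    tied = [h for h in sampled if g.nodes[h]["frequency"] == max_freq]
    if len(tied) == 1:
        return tied[0]

    def ecc(h):
        comp_nodes = nx.node_connected_component(g, h)
        return nx.eccentricity(g.subgraph(comp_nodes), v=h)

    return min(tied, key=lambda h: (ecc(h), h))


def write_edge_list(net: HaplotypeNetwork, path) -> None:
    """CSV edge-list alternative to GraphML (source,target,steps)."""
    with open(path, "w") as fh:
        fh.write("source,target,steps\n")
        for u, v, data in net.graph.edges(data=True):
            fh.write(f"{u},{v},{data.get('steps', 1)}\n")


def contracted_step_counts(net: HaplotypeNetwork) -> dict[tuple[str, str], int]:
    """Shortest-path step counts between sampled nodes, medians contracted."""
    g = net.graph
    out = {}
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for a, b in itertools.combinations(sorted(net.sampled_nodes), 2):
        if b in lengths.get(a, {}):
            out[(a, b)] = lengths[a][b]
    return out
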