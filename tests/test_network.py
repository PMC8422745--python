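import itertools

import networkx as nx
import numpy as np
import pytest

from coipopgen.haplotypes import HaplotypeTable, collapse_haplotypes
from coipopgen.network import (
    build_tcs_network,
    central_haplotype,
    contracted_step_counts,
    hamming,
    parsimony_connection_limit,
    parsimony_probability,
)


def _table(seq_counts):
    """Build a HaplotypeTable from {sequence: count} in one population."""
    ordered = sorted(seq_counts.items(), key=lambda kv: -kv[1])
    haps = tuple((f"Hap_{i+1}", s) for i, (s, _) in enumerate(ordered))
    counts = {f"Hap_{i+1}": {"P": c} for i, (_, c) in enumerate(ordered)}
    return HaplotypeTable(haps, counts)


def parsimony_probability_oracle(j, m, kmax=3000):
    """Matrix-power evaluation of the same probability model, written
    independently of the iterative implementation."""
    p = 1.0 / (1.0 + j)
    size = min(m, 4 * j + 40) + 1
    T = np.zeros((size, size))
    for x in range(size):
        up = (m - x) / m if x < size - 1 else 0.0
        down = x / (3 * m)
        T[x, min(x + 1, size - 1)] += up
        T[x, max(x - 1, 0)] += down
        T[x, x] += 1 - up - down
    powers = np.zeros(size)
    powers[0] = 1.0
    num = den = 0.0
    for k in range(kmax):
        prior = p * (1 - p) ** k
        if k >= j:
            term = prior * powers[j]
            den += term
            if k == j:
                num = term
        powers = powers @ T
    return num / den


@pytest.mark.parametrize("j,m", [(1, 50), (3, 100), (5, 674), (8, 674)])
def test_parsimony_probability_matches_oracle(j, m):
    assert parsimony_probability(j, m) == pytest.approx(
        parsimony_probability_oracle(j, m), abs=1e-6
    )


def test_connection_limit_boundaries():
    assert parsimony_connection_limit(10, confidence=0.0) == 10
    with pytest.raises(ValueError):
        parsimony_connection_limit(0)


def test_connection_limit_monotone_in_length():
    limits = [parsimony_connection_limit(L) for L in (50, 200, 674, 1200)]
    assert limits == sorted(limits)
    assert limits[0] >= 1


def test_two_haplotypes_one_step():
    net = build_tcs_network(_table({"AAAA": 3, "AAAT": 1}), limit=5)
    assert net.graph.number_of_nodes() == 2
    assert net.graph.number_of_edges() == 1
    assert not net.median_nodes


def test_median_node_inserted_for_two_steps():
    # A-B one step, B-C two steps, A-C three steps
    net = build_tcs_network(
        _table({"AAAA": 3, "AAAT": 2, "ATTT": 1}), limit=5
    )
    assert len(net.median_nodes) == 1
    assert net.graph.number_of_nodes() == 4
    # every edge is exactly one step
    assert all(d["steps"] == 1 for _, _, d in net.graph.edges(data=True))


def test_limit_respected():
    net = build_tcs_network(_table({"AAAAAA": 1, "TTTTTT": 1}), limit=3)
    assert net.graph.number_of_edges() == 0


def test_star_hub_is_central():
    center = "AAAAA"
    tips = ["TAAAA", "ATAAA", "AATAA", "AAATA", "AAAAT"]
    table = _table({center: 10, **{t: 1 for t in tips}})
    net = build_tcs_network(table, limit=5)
    assert central_haplotype(net) == "Hap_1"
    assert net.graph.nodes["Hap_1"]["sequence"] == center


def test_single_haplotype_network():
    net = build_tcs_network(_table({"ACGT": 5}), limit=3)
    assert central_haplotype(net) == "Hap_1"
    assert net.graph.number_of_nodes() == 1


def test_contracted_paths_recover_hamming_distances():
    table = _table({"AAAA": 4, "AAAT": 2, "AATT": 1, "TAAA": 1})
    net = build_tcs_network(table, limit=4)
    seq = {h: s for h, s in table.haplotypes}
    steps = contracted_step_counts(net)
    for (a, b), st in steps.items():
        assert st >= hamming(seq[a], seq[b])
    # adjacent sampled pairs reached through medians match exactly
    assert steps[("Hap_1", "Hap_3")] == hamming(seq["Hap_1"], seq["Hap_3"])


def test_edge_list_export(tmp_path):
    from coipopgen.network import write_edge_list

    net = build_tcs_network(_table({"AAAA": 3, "AAAT": 1}), limit=5)
    p = tmp_path / "edges.csv"
    write_edge_list(net, p)
    lines = p.read_text().splitlines()
    assert lines[0] == "source,target,steps"
    assert len(lines) == 2 and lines[1].endswith(",1")


def test_tree_like_network_edge_count(paper_like_dataset):
    aln, pm, _ = paper_like_dataset
    table = collapse_haplotypes(aln, pm)
    net = build_tcs_network(table)
    g = net.graph
    assert nx.is_connected(g)
    # sampled frequencies sum to the sample size
    assert sum(g.nodes[h]["frequency"] for h in net.sampled_nodes) == aln.n
    # node bookkeeping: sampled + medians
    assert g.number_of_nodes() == len(net.sampled_nodes) + len(net.median_nodes)
    # spanning structure: at least a tree over all nodes
    assert g.number_of_edges() >= g.number_of_nodes() - 1
    assert central_haplotype(net) == "Hap_1"
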