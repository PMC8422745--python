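import itertools
import math

import numpy as np
import pytest

from conftest import random_alignment
from coipopgen.datasets import load_ds_matrix
from coipopgen.distances import (
    DistanceMatrix,
    SaturationError,
    between_population_distance,
    is_isolated_at_root,
    k2p_distance,
    midpoint_root,
    neighbor_joining,
    upgma,
)
from coipopgen.io import Alignment, PopulationMap


def test_k2p_identity():
    assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_k2p_closed_forms():
    # P = 0.1, Q = 0: -1/2 ln(0.8)
    a = "A" * 10
    b = "G" + "A" * 9
    assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
    assert k2p_distance(a, b) == pytest.approx(0.11157, abs=5e-6)
    # P = 0, Q = 0.1: -1/2 ln(0.9) - 1/4 ln(0.8)
    c = "C" + "A" * 9
    want = -0.5 * math.log(0.9) - 0.25 * math.log(0.8)
    assert k2p_distance(a, c) == pytest.approx(want, abs=1e-12)
    assert k2p_distance(a, c) == pytest.approx(0.10847, abs=5e-6)


def test_k2p_pairwise_deletion():
    # the N site is dropped for this pair only
    assert k2p_distance("ANAA", "AGAA") == 0.0


def test_k2p_saturation_error():
    with pytest.raises(SaturationError):
        k2p_distance("AAAA", "GGGG")  # P = 1


def test_k2p_dominates_p_distance(rng):
    for _ in range(30):
        L = 60
        a = "".join(rng.choice(list("ACGT"), size=L))
        b = list(a)
        nmut = int(rng.integers(1, 12))
        sites = rng.choice(L, size=nmut, replace=False)
        for s in sites:
            b[s] = rng.choice([x for x in "ACGT" if x != a[s]])
        b = "".join(b)
        p_dist = sum(x != y for x, y in zip(a, b)) / L
        assert k2p_distance(a, b) >= p_dist - 1e-12


def test_between_population_distance_single_pair_reduction():
    # two monomorphic populations two transitions apart over 10 sites
    aln = Alignment((
        ("a1", "AAAAAAAAAA"), ("a2", "AAAAAAAAAA"),
        ("b1", "GGAAAAAAAA"), ("b2", "GGAAAAAAAA"),
    ))
    pm = PopulationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    dm, within = between_population_distance(aln, pm)
    expect = k2p_distance("AAAAAAAAAA", "GGAAAAAAAA")
    assert dm.values[0, 1] == pytest.approx(expect, abs=1e-12)
    assert within == {"A": 0.0, "B": 0.0}


def test_between_equals_within_for_split_population(rng):
    # low-divergence pool (random sequences would saturate the correction)
    base = "".join(rng.choice(list("ACGT"), size=60))
    seqs = []
    for _ in range(8):
        s = list(base)
        for site in rng.choice(60, size=3, replace=False):
            s[site] = rng.choice([x for x in "ACGT" if x != base[site]])
        seqs.append("".join(s))
    aln = Alignment(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
    # same pool labelled as two populations
    pm = PopulationMap({f"s{i}": ("X" if i % 2 else "Y") for i in range(8)})
    dm, within = between_population_distance(aln, pm)
    mean_within = np.mean(list(within.values()))
    assert dm.values[0, 1] == pytest.approx(mean_within, rel=0.5)
    # and the net version is near zero
    dm_net, _ = between_population_distance(aln, pm, net=True)
    assert dm_net.values[0, 1] < dm.values[0, 1]


def test_upgma_hand_example():
    m = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = upgma(DistanceMatrix(("A", "B", "C"), m))
    depths = tree.root_to_leaf_depths()
    # ultrametric with root height 2, cherry (A,B) at height 1
    assert all(abs(dep - 2.0) < 1e-9 for dep in depths.values())
    newick = tree.to_newick()
    assert "(A:1,B:1):1" in newick and "C:2" in newick


def test_upgma_ultrametric_property(rng):
    n = 7
    m = rng.uniform(1.0, 10.0, size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    tree = upgma(DistanceMatrix(tuple("ABCDEFG"), m))
    depths = list(tree.root_to_leaf_depths().values())
    assert max(depths) - min(depths) < 1e-9


def test_nj_recovers_additive_tree_exactly():
    # tree ((A:1,B:2):3,C:4,D:5) pairwise path lengths
    d = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
         ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
    labels = ["A", "B", "C", "D"]
    m = np.zeros((4, 4))
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        m[i, j] = m[j, i] = d[(a, b)]
    tree = neighbor_joining(DistanceMatrix(tuple(labels), m))
    ld = tree.leaf_distances()
    for (a, b), v in d.items():
        assert ld.loc[a, b] == pytest.approx(v, abs=1e-9)


def test_nj_matches_skbio_on_random_matrices(rng):
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    for _ in range(3):
        n = 6
        m = rng.uniform(0.5, 5.0, size=(n, n))
        m = np.triu(m, 1)
        m = m + m.T
        labels = tuple("ABCDEF")
        mine = neighbor_joining(DistanceMatrix(labels, m)).leaf_distances()
        sk_tree = sk_nj(SkDM(m, ids=list(labels)))
        for a, b in itertools.combinations(labels, 2):
            want = sk_tree.find(a).distance(sk_tree.find(b))
            assert mine.loc[a, b] == pytest.approx(want, abs=1e-9)


def test_tree_construction_deterministic():
    dm = load_ds_matrix()
    n1 = neighbor_joining(dm).to_newick()
    n2 = neighbor_joining(dm).to_newick()
    u1 = upgma(dm).to_newick()
    u2 = upgma(dm).to_newick()
    assert n1 == n2 and u1 == u2


def test_published_ds_matrix_separates_jn():
    dm = load_ds_matrix()
    assert is_isolated_at_root(upgma(dm), "JN")
    nj_tree = midpoint_root(neighbor_joining(dm))
    assert is_isolated_at_root(nj_tree, "JN")


def test_asymmetric_matrix_rejected():
    m = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError):
        DistanceMatrix(("A", "B"), m)
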