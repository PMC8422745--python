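import itertools
import math

import numpy as np
import pytest
from scipy import stats

from coipopgen.io import Alignment
from coipopgen.simulate import SimulationConfig, simulate_coalescent
from coipopgen.structure import (
    amova,
    pairwise_difference_matrix,
    pairwise_fst,
    samova,
    sequential_bonferroni,
)


def amova_oracle_one_level(d, pops):
    """Direct expected-mean-square evaluation, plain python loops only."""
    labels = sorted(set(pops))
    N = len(pops)
    P = len(labels)
    ss_total = sum(
        d[i][j] for i in range(N) for j in range(i + 1, N)
    ) / N
    ss_wp = 0.0
    for lab in labels:
        idx = [i for i, p in enumerate(pops) if p == lab]
        ss_wp += sum(
            d[i][j] for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    ss_ap = ss_total - ss_wp
    sizes = [pops.count(lab) for lab in labels]
    sigma_c = ss_wp / (N - P)
    n_prime = (N - sum(s * s for s in sizes) / N) / (P - 1)
    sigma_a = (ss_ap / (P - 1) - sigma_c) / n_prime
    return sigma_a, sigma_c, sigma_a / (sigma_a + sigma_c)


def test_pairwise_difference_matrix_hand_count():
    aln = Alignment((("x", "ACGT"), ("y", "AGGA")))
    d = pairwise_difference_matrix(aln)
    assert d[0, 1] == 2  # positions 2 and 4
    assert d[0, 0] == d[1, 1] == 0
    assert np.allclose(d, d.T)


def test_amova_matches_bruteforce_small_instances(rng):
    for trial in range(5):
        n = int(rng.integers(8, 13))
        pops = ["A"] * (n // 2) + ["B"] * (n - n // 2 - 2) + ["C"] * 2
        d = rng.integers(0, 6, size=(n, n)).astype(float)
        d = np.triu(d, 1)
        d = d + d.T
        res = amova(d, pops)
        sa, sc, phi = amova_oracle_one_level(d.tolist(), pops)
        assert res.variance_components["among_populations"] == pytest.approx(sa, abs=1e-12)
        assert res.variance_components["within_populations"] == pytest.approx(sc, abs=1e-12)
        assert res.phi_ST == pytest.approx(phi, abs=1e-12)


def test_fixed_difference_populations_give_phist_one():
    seqs = [("a%d" % i, "AAAA") for i in range(4)] + [
        ("b%d" % i, "AAAT") for i in range(4)
    ]
    aln = Alignment(tuple(seqs))
    d = pairwise_difference_matrix(aln)
    pops = ["A"] * 4 + ["B"] * 4
    res = amova(d, pops)
    assert res.phi_ST == pytest.approx(1.0)
    assert res.percent_variation["among_populations"] == pytest.approx(100.0)
    assert sum(res.percent_variation.values()) == pytest.approx(100.0, abs=1e-2)


def test_panmictic_pool_has_null_phist():
    cfg = SimulationConfig(n_demes=1, sample_sizes=(40,), theta=3.0,
                           infinite_sites=True, seed=3)
    aln, _, _ = simulate_coalescent(cfg)
    d = pairwise_difference_matrix(aln)
    pops = ["X"] * 20 + ["Y"] * 20  # arbitrary split of one pool
    res = amova(d, pops, permutations=200, seed=3)
    assert abs(res.phi_ST) < 0.15
    assert res.p_values["Phi_ST"] > 0.05


def test_permutation_pvalues_uniform_under_null():
    # needs enough polymorphism that Phi_ST is effectively continuous;
    # near-monomorphic draws create ties (conservative p = 1 atoms)
    from coipopgen.haplotypes import site_summary

    rng = np.random.default_rng(9)
    pvals = []
    while len(pvals) < 200:
        cfg = SimulationConfig(n_demes=1, sample_sizes=(20,), theta=8.0,
                               infinite_sites=True, seed=0)
        aln, _, _ = simulate_coalescent(cfg, rng)
        if site_summary(aln).S < 5:
            continue
        d = pairwise_difference_matrix(aln)
        pops = ["X"] * 10 + ["Y"] * 10
        res = amova(d, pops, permutations=99, seed=int(rng.integers(2**31 - 1)))
        pvals.append(res.p_values["Phi_ST"])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_two_level_degenerate_groups():
    seqs = [(f"s{i}", s) for i, s in enumerate(
        ["AAAA", "AAAT", "AAAA", "AATT", "ATTT", "AATT"]
    )]
    aln = Alignment(tuple(seqs))
    d = pairwise_difference_matrix(aln)
    pops = ["A", "A", "A", "B", "B", "B"]
    one = amova(d, pops)
    two = amova(d, pops, groups=[["A"], ["B"]])
    assert two.phi_SC is None  # no populations within groups to compare
    assert two.phi_CT == pytest.approx(one.phi_ST, abs=1e-9)


def test_population_of_one_rejected():
    aln = Alignment((("a", "AAAA"), ("b", "AAAT"), ("c", "AATT")))
    d = pairwise_difference_matrix(aln)
    with pytest.raises(ValueError, match="B"):
        amova(d, ["A", "A", "B"])


def test_pairwise_fst_diagonal_and_symmetry(paper_like_dataset):
    aln, pm, _ = paper_like_dataset
    d = pairwise_difference_matrix(aln)
    pops = [pm.assignments[s] for s in aln.sample_ids]
    res = pairwise_fst(d, pops)
    assert np.allclose(np.diag(res.values), 0.0)
    assert np.allclose(res.values, res.values.T)
    # the isolated deme is strongly differentiated from everything
    j = res.labels.index("P7")
    others = [i for i in range(len(res.labels)) if i != j]
    assert all(res.values[j, i] > 0.4 for i in others)


def test_samova_isolates_diverged_deme():
    cfg = SimulationConfig(
        n_demes=3, sample_sizes=(15, 15, 15), L=800, theta=2.0,
        migration=10.0, diverged_deme=(2, 6.0), infinite_sites=True, seed=5,
    )
    aln, pm, _ = simulate_coalescent(cfg)
    d = pairwise_difference_matrix(aln)
    pops = [pm.assignments[s] for s in aln.sample_ids]
    res = samova(d, pops, K=2)
    assert (("P3",) in res.groups) or (["P3"] in [list(g) for g in res.groups])


def test_samova_annealing_agrees_with_exhaustive(paper_like_dataset):
    aln, pm, _ = paper_like_dataset
    d = pairwise_difference_matrix(aln)
    pops = [pm.assignments[s] for s in aln.sample_ids]
    for k in (2, 3):
        ex = samova(d, pops, K=k)
        an = samova(d, pops, K=k, force_annealing=True, seed=11,
                    n_starts=10, anneal_steps=300)
        assert an.phi_CT == pytest.approx(ex.phi_CT, abs=1e-12)
        assert sorted(map(sorted, an.groups)) == sorted(map(sorted, ex.groups))


def test_sequential_bonferroni_hand_case():
    # Holm: sorted p (.01,.02,.04) with m=3 -> (.03,.04,.04)
    adj = sequential_bonferroni(np.array([0.02, 0.04, 0.01]))
    assert np.allclose(adj, [0.04, 0.04, 0.03])
    assert sequential_bonferroni(np.array([0.9, 0.8])).max() == 1.0


def test_samova_k_out_of_range(paper_like_dataset):
    aln, pm, _ = paper_like_dataset
    d = pairwise_difference_matrix(aln)
    pops = [pm.assignments[s] for s in aln.sample_ids]
    with pytest.raises(ValueError):
        samova(d, pops, K=1)
    with pytest.raises(ValueError):
        samova(d, pops, K=7)
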