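import filecmp
import math

import numpy as np
import pytest

from coipopgen.diversity import mean_pairwise_differences, population_diversity
from coipopgen.haplotypes import site_summary
from coipopgen.simulate import (
    PAPER_LIKE,
    SimulationConfig,
    make_fixture,
    simulate_coalescent,
    single_population_stats,
)
from coipopgen.structure import pairwise_difference_matrix, pairwise_fst


def test_theta_zero_gives_monomorphic_sample():
    cfg = SimulationConfig(n_demes=1, sample_sizes=(12,), theta=0.0, seed=4)
    aln, _, _ = simulate_coalescent(cfg)
    assert len(set(aln.sequences)) == 1
    assert site_summary(aln).S == 0


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_demes=2, sample_sizes=(5,))
    with pytest.raises(ValueError):
        SimulationConfig(n_demes=2, sample_sizes=(5, 5))  # no migration/split
    with pytest.raises(ValueError):
        SimulationConfig(expansion=(0.0, 10.0))


def test_seed_required():
    cfg = SimulationConfig(n_demes=1, sample_sizes=(5,), theta=1.0)
    with pytest.raises(ValueError):
        simulate_coalescent(cfg)


def test_fixture_deterministic(tmp_path):
    f1, p1 = make_fixture(tmp_path / "a", seed=7)
    f2, p2 = make_fixture(tmp_path / "b", seed=7)
    assert filecmp.cmp(f1, f2, shallow=False)
    assert filecmp.cmp(p1, p2, shallow=False)
    f3, _ = make_fixture(tmp_path / "c", seed=8)
    assert not filecmp.cmp(f1, f3, shallow=False)


def test_watterson_theta_calibration():
    rng = np.random.default_rng(11)
    n, theta = 20, 2.0
    a1 = sum(1.0 / i for i in range(1, n))
    est = []
    for _ in range(500):
        S, _, _ = single_population_stats(n, rng, theta=theta)
        est.append(S / a1)
    assert np.mean(est) == pytest.approx(theta, rel=0.10)


def test_mean_pairwise_differences_match_theta():
    rng = np.random.default_rng(12)
    ks = [single_population_stats(15, rng, theta=3.0)[1] for _ in range(500)]
    assert np.mean(ks) == pytest.approx(3.0, rel=0.10)


def test_msprime_cross_validation():
    """Independent coalescent oracle: S distribution against msprime."""
    import msprime

    rng = np.random.default_rng(13)
    n, theta, reps = 20, 2.0, 400
    mine = [single_population_stats(n, rng, theta=theta)[0] for _ in range(reps)]
    other = []
    # haploid coalescent with time in units of N generations: ploidy 1,
    # population size 1, per-locus mutation rate theta/2
    reps_ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0,
        num_replicates=reps, random_seed=13,
    )
    for ts in reps_ts:
        mts = msprime.sim_mutations(
            ts, rate=theta / 2, random_seed=int(rng.integers(1, 2**31)),
            discrete_genome=False,
        )
        other.append(mts.num_sites)
    assert np.mean(mine) == pytest.approx(np.mean(other), rel=0.10)
    assert np.std(mine) == pytest.approx(np.std(other), rel=0.25)


def test_fixture_matches_study_conditions(paper_like_dataset):
    aln, pm, truth = paper_like_dataset
    assert aln.n == 326 and aln.length == 674
    assert pm.sizes() == {
        "P1": 46, "P2": 44, "P3": 47, "P4": 47, "P5": 48, "P6": 48, "P7": 46
    }
    div = population_diversity(aln, pm)
    per_pop = div[div["population"] != "pooled"]
    assert per_pop["Hd"].between(0.2, 0.85).all()
    assert per_pop["pi"].between(0.0003, 0.003).all()
    d = pairwise_difference_matrix(aln)
    pops = [pm.assignments[s] for s in aln.sample_ids]
    fst = pairwise_fst(d, pops)
    j = fst.labels.index("P7")
    assert all(fst.values[j, i] > 0.4 for i in range(len(fst.labels)) if i != j)
    assert truth["tau_true"] == pytest.approx(
        PAPER_LIKE.theta * PAPER_LIKE.expansion[0]
    )


def test_expansion_signal_in_fixture(paper_like_dataset):
    """Pooling the six connected demes shows the expansion footprint."""
    from coipopgen.haplotypes import included_sites, restrict
    from coipopgen.neutrality import tajimas_d

    aln, pm, _ = paper_like_dataset
    sites = included_sites(aln)
    seqs = [
        restrict(s, sites)
        for sid, s in aln.records
        if pm.assignments[sid] != "P7"
    ]
    sub_S = site_summary(
        type(aln)(tuple((f"x{i}", s) for i, s in enumerate(seqs)))
    ).S
    k = mean_pairwise_differences(seqs)
    assert tajimas_d(len(seqs), sub_S, k) < 0
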