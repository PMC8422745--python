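import math
from functools import lru_cache

import numpy as np
import pytest

from coipopgen.neutrality import (
    NeutralityResult,
    UndefinedStatistic,
    ewens_log_pmf,
    fus_fs,
    neutrality_tests,
    tajimas_d,
    tajimas_d_pvalue,
)
from coipopgen.simulate import SimulationConfig, simulate_coalescent, \
    single_population_stats


def tajima_oracle(n, S, K):
    """Independent transcription of the 1989 normalizing constants."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1, e2 = c1 / a1, c2 / (a1 * a1 + a2)
    return (K - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_zero_numerator():
    n = 10
    a1 = sum(1.0 / i for i in range(1, n))
    assert tajimas_d(n, 5, 5 / a1) == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_reference_value():
    assert tajimas_d(4, 1, 0.5) == pytest.approx(-0.612, abs=5e-4)
    for n, S, K in [(10, 5, 2.0), (48, 25, 1.885), (40, 12, 1.2)]:
        assert tajimas_d(n, S, K) == pytest.approx(tajima_oracle(n, S, K), abs=1e-12)


def test_tajimas_d_undefined_when_no_segregating_sites():
    with pytest.raises(UndefinedStatistic):
        tajimas_d(10, 0, 0.0)


# --- Fu's Fs / Ewens sampling -------------------------------------------


def _partitions(n, max_part=None):
    """All integer partitions of n (as sorted tuples)."""
    if n == 0:
        yield ()
        return
    if max_part is None:
        max_part = n
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def ewens_tail_oracle(n, theta, k_obs):
    """P(K >= k_obs) by exact enumeration of Ewens partition probabilities."""
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    total = 0.0
    for part in _partitions(n):
        k = len(part)
        if k < k_obs:
            continue
        counts = {}
        for j in part:
            counts[j] = counts.get(j, 0) + 1
        denom = 1.0
        for j, a in counts.items():
            denom *= (j**a) * math.factorial(a)
        total += math.factorial(n) * theta**k / (rising * denom)
    return total


def test_fs_exact_small_case():
    # n=3: |s(3,k)| = (2, 3, 1) -> S' = P(K >= 2) = 4/6
    assert fus_fs(3, 1.0, 2) == pytest.approx(math.log(2.0), abs=1e-12)


def test_fs_boundary_k1_is_infinite():
    assert fus_fs(5, 0.7, 1) == math.inf


def test_fs_rejects_bad_inputs():
    with pytest.raises(ValueError):
        fus_fs(5, 0.0, 2)
    with pytest.raises(ValueError):
        fus_fs(5, 1.0, 0)


@pytest.mark.parametrize("n,theta", [(4, 0.5), (6, 1.3), (8, 2.7)])
def test_fs_matches_partition_enumeration(n, theta):
    for k_obs in range(2, n + 1):
        sp = ewens_tail_oracle(n, theta, k_obs)
        expected = math.log(sp) - math.log1p(-sp)
        assert fus_fs(n, theta, k_obs) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("n", [2, 10, 25, 50])
def test_ewens_pmf_sums_to_one(n):
    for theta in (0.1, 1.0, 7.5):
        assert np.exp(ewens_log_pmf(n, theta)).sum() == pytest.approx(1.0, abs=1e-9)


# --- simulation p-values -------------------------------------------------


def test_pvalue_of_median_statistic_near_half():
    rng = np.random.default_rng(17)
    sims = []
    for _ in range(400):
        s, k, _ = single_population_stats(20, rng, S=6)
        sims.append(tajimas_d(20, s, k))
    med = float(np.median(sims))
    p = tajimas_d_pvalue(20, 6, med, reps=400, rng=np.random.default_rng(18))
    assert 0.35 < p < 0.65


def test_expansion_produces_significant_negative_d():
    # recent, strong expansion: a nearly star-like genealogy
    cfg = SimulationConfig(
        n_demes=1, sample_sizes=(50,), L=800, theta=30.0,
        expansion=(0.05, 500.0), infinite_sites=True, seed=1,
    )
    aln, pm, _ = simulate_coalescent(cfg)
    res = neutrality_tests(aln, pm, reps=500, seed=1, pooled=False)
    (r,) = res
    assert r.D is not None and r.D < 0
    assert r.D_p < 0.05
    assert r.Fs < 0  # haplotype excess


def test_monomorphic_population_signalled():
    cfg = SimulationConfig(n_demes=1, sample_sizes=(10,), theta=0.0, seed=2)
    aln, pm, _ = simulate_coalescent(cfg)
    (r,) = neutrality_tests(aln, pm, reps=100, seed=3, pooled=False)
    assert r.S == 0 and r.D is None and r.Fs is None
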