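"""Tajima's D and Fu's Fs with coalescent-simulation p-values.

Both statistics are one-tailed (lower tail): negative values indicate an
excess of rare variants / haplotypes, as expected after a recent expansion.
Fu's Fs conventionally counts as "significant at the 5% level" only when
p < 0.02; the raw p is always reported and the threshold is left to the
caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .haplotypes import included_sites, restrict, site_summary
from .diversity import mean_pairwise_differences
from .io import Alignment, PopulationMap
from .simulate import single_population_stats


class UndefinedStatistic(ValueError):
    """The statistic is undefined for these inputs (e.g. S = 0)."""


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 normalizing constants of Tajima's (1989) D."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(n: int, S: int, K: float) -> float:
    """D = (K - S/a1) / sqrt(e1*S + e2*S*(S-1))."""
    if S < 1:
        raise UndefinedStatistic("Tajima's D is undefined when S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (K - S / c["a1"]) / math.sqrt(var)


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind).

    Recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)| evaluated in log space so
    rows stay finite well past n = 326.
    """
    row = [-math.inf, 0.0]  # n = 1: |s(1,0)| = 0, |s(1,1)| = 1
    for m in range(1, n):
        new = [-math.inf] * (m + 2)
        logm = math.log(m)
        for k in range(1, m + 2):
            a = row[k] + logm if k <= m else -math.inf
            b = row[k - 1] if k - 1 <= m else -math.inf
            new[k] = np.logaddexp(a, b)
        row = new
    return tuple(row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling distribution."""
    if n < 1 or theta <= 0:
        raise ValueError("need n >= 1 and theta > 0")
    log_rising = sum(math.log(theta + i) for i in range(n))
    stirling = _log_stirling_row(n)
    ks = np.arange(1, n + 1)
    return np.array(
        [stirling[k] + k * math.log(theta) - log_rising for k in ks]
    )


def fus_fs(n: int, theta: float, k_obs: int) -> float:
    """Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta, n) under Ewens.

    ``theta`` is the pi-based estimate (the mean pairwise difference K).
    Returns signed infinity when S' is numerically 1 or 0 (k_obs = 1 gives
    S' = 1 exactly, reported as +inf).
    """
    if k_obs < 1 or k_obs > n:
        raise ValueError("k_obs must be in 1..n")
    if theta <= 0:
        raise ValueError("Fu's Fs needs theta > 0")
    if k_obs == 1:
        return math.inf  # S' = 1 exactly
    logp = ewens_log_pmf(n, theta)
    # S' = sum_{k >= k_obs} P(K = k), in log space
    tail = logp[k_obs - 1:]
    log_sp = float(np.logaddexp.reduce(tail))
    if log_sp >= -1e-12:  # S' == 1 to numerical precision
        return math.inf
    sp = math.exp(log_sp)
    if sp <= 0.0:
        return -math.inf
    # ln(S') - ln(1 - S'), with log1p for the complement
    return log_sp - math.log1p(-sp)


def tajimas_d_pvalue(
    n: int, S: int, d_obs: float, reps: int, rng: np.random.Generator
) -> float:
    """Lower-tail p for D by coalescent simulation conditional on S."""
    if reps < 100:
        raise ValueError("use at least 100 replicates")
    hits = 0
    for _ in range(reps):
        s_sim, k_sim, _ = single_population_stats(n, rng, S=S)
        hits += tajimas_d(n, s_sim, k_sim) <= d_obs
    return hits / reps


def fus_fs_pvalue(
    n: int, theta: float, fs_obs: float, reps: int, rng: np.random.Generator
) -> float:
    """Lower-tail p for Fs by coalescent simulation driven by theta-pi."""
    if reps < 100:
        raise ValueError("use at least 100 replicates")
    hits = 0
    for _ in range(reps):
        _, k_sim, hap_sim = single_population_stats(n, rng, theta=theta)
        if k_sim <= 0:
            fs_sim = math.inf  # monomorphic draw: maximally non-negative
        else:
            fs_sim = fus_fs(n, k_sim, hap_sim)
        hits += fs_sim <= fs_obs
    return hits / reps


@dataclass(frozen=True)
class NeutralityResult:
    population: str
    n: int
    S: int
    K: float
    k_obs: int
    D: float | None
    D_p: float | None
    Fs: float | None
    Fs_p: float | None


def neutrality_tests(
    aln: Alignment,
    pm: PopulationMap,
    reps: int = 10_000,
    seed: int | None = None,
    populations: list[str] | None = None,
    pooled: bool = True,
) -> list[NeutralityResult]:
    """Tajima's D and Fu's Fs per population (plus a pooled row)."""
    if seed is None:
        raise ValueError("a seed is required for simulation p-values")
    rng = np.random.default_rng(seed)
    pm.require_complete(aln)
    sites = included_sites(aln)
    groups: list[tuple[str, list[str]]] = [
        (p, list(pm.samples_in(p))) for p in (populations or pm.populations)
    ]
    if pooled:
        groups.append(("pooled", list(aln.sample_ids)))
    results = []
    for label, ids in groups:
        wanted = set(ids)
        seqs = [restrict(s, sites) for sid, s in aln.records if sid in wanted]
        n = len(seqs)
        sub = Alignment.from_pairs((f"x{i}", s) for i, s in enumerate(seqs))
        S = site_summary(sub).S
        K = mean_pairwise_differences(seqs)
        k_obs = len(set(seqs))
        if S < 1:
            results.append(
                NeutralityResult(label, n, S, K, k_obs, None, None, None, None)
            )
            continue
        d = tajimas_d(n, S, K)
        d_p = tajimas_d_pvalue(n, S, d, reps, rng)
        fs = fus_fs(n, K, k_obs)
        fs_p = fus_fs_pvalue(n, K, fs, reps, rng)
        results.append(NeutralityResult(label, n, S, K, k_obs, d, d_p, fs, fs_p))
    return results
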