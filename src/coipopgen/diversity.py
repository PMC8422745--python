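"""Per-population molecular diversity indices.

Haplotype diversity Hd with its Nei (1987) large-sample standard deviation,
and nucleotide diversity pi (p-distance based, complete deletion of
missing-data columns) with the Nei (1987) no-recombination total variance.
K is the raw mean number of pairwise differences; pi = K / included sites.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .haplotypes import collapse_haplotypes, included_sites, restrict, site_summary
from .io import Alignment, PopulationMap


@dataclass(frozen=True)
class DiversityStats:
    population: str
    n: int
    h: int
    h_prime: int
    S: int
    K: float
    Hd: float
    Hd_sd: float
    pi: float
    pi_sd: float


def haplotype_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Hd = n/(n-1) * (1 - sum p_i^2) and its sampling SD.

    The variance is Nei (1987)'s large-sample heterozygosity variance
    2/(n(n-1)) * [2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2].
    """
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = np.asarray(counts, dtype=float) / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum2)
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return hd, float(np.sqrt(max(var, 0.0)))


def mean_pairwise_differences(seqs: Sequence[str]) -> float:
    """K: mean Hamming distance over all n(n-1)/2 sequence pairs."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    total = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(1 for x, y in zip(a, b) if x != y)
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(seqs: Sequence[str], n_sites: int | None = None
                         ) -> tuple[float, float, float]:
    """Return (pi, pi_sd, K) for one population's sequences.

    ``seqs`` must already be restricted to included sites (no missing data);
    ``n_sites`` defaults to their length. pi = K / n_sites; its SD is the
    Nei (1987) total variance under no recombination,
    V(pi) = (n+1) pi / (3 (n-1) L) + 2 (n^2 + n + 3) pi^2 / (9 n (n-1)).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    L = n_sites if n_sites is not None else len(seqs[0])
    if L < 1:
        raise ValueError("no included sites")
    k = mean_pairwise_differences(seqs)
    pi = k / L
    var = (n + 1) * pi / (3.0 * (n - 1) * L) + 2.0 * (n**2 + n + 3) * pi**2 / (
        9.0 * n * (n - 1)
    )
    return pi, float(np.sqrt(max(var, 0.0))), k


def population_diversity(aln: Alignment, pm: PopulationMap) -> pd.DataFrame:
    """Per-population diversity table plus a pooled 'mean' row.

    Sites are excluded by complete deletion computed on the FULL alignment,
    so per-population statistics are comparable across populations. The
    pooled row treats all sequences as one sample.
    """
    pm.require_complete(aln)
    sites = included_sites(aln)
    table = collapse_haplotypes(aln, pm)
    from .haplotypes import shared_and_unique

    hu = shared_and_unique(table).set_index("population")
    rows = []
    groups = list(pm.populations) + [None]  # None = pooled
    for pop in groups:
        if pop is None:
            seqs = [restrict(s, sites) for s in aln.sequences]
            label = "pooled"
        else:
            ids = set(pm.samples_in(pop))
            seqs = [restrict(s, sites) for sid, s in aln.records if sid in ids]
            label = pop
        sub = Alignment.from_pairs(
            (f"x{i}", s) for i, s in enumerate(seqs)
        )
        ss = site_summary(sub)
        hd_counts = list(Counter(seqs).values())
        hd, hd_sd = haplotype_diversity(hd_counts)
        pi, pi_sd, k = nucleotide_diversity(seqs, len(sites))
        rows.append(
            DiversityStats(
                population=label,
                n=len(seqs),
                h=len(hd_counts),
                h_prime=int(hu.loc[pop, "h_prime"]) if pop is not None else 0,
                S=ss.S,
                K=k,
                Hd=hd,
                Hd_sd=hd_sd,
                pi=pi,
                pi_sd=pi_sd,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.attrs["excluded_sites"] = aln.length - len(sites)
    return df
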