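"""Haploid coalescent simulator for single-locus mtDNA-style data.

The simulator generates samples under a backward-time coalescent with

* an arbitrary number of demes exchanging migrants under a symmetric
  island model,
* an optional sudden (stepwise) expansion affecting every deme: forward in
  time, all demes grew by ``fold`` at ``time`` (in units of N generations,
  where N is the present-day haploid deme size), and
* an optional fully isolated ("diverged") deme that split from the rest at
  ``split_time``; at the split, looking backwards, every lineage merges into
  a single ancestral deme.

Time is measured in units of N generations; ``theta = 2*N*u`` is the
per-deme scaled mutation rate for the whole locus, so a lineage mutates at
rate ``theta/2`` per unit time. Mutations follow a finite-sites model with a
configurable transition:transversion ratio (default 10:1, mimicking COI), or
an infinite-sites model where each mutation hits a fresh site — the latter
is the engine behind neutrality-test p-values and mismatch bootstraps.

Under the island model with ``d`` demes and scaled migration ``M`` (each
lineage migrates at rate ``M/2``), the expected pairwise Phi_ST is
``(d-1)/(M*d + d - 1)``, i.e. ``1/(1+2M)`` for two demes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Alignment, PopulationMap, write_alignment

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    n_demes: int = 1
    sample_sizes: tuple[int, ...] = (20,)
    L: int = 674
    theta: float = 1.0
    expansion: tuple[float, float] | None = None  # (time, fold change)
    migration: float | None = None  # scaled island-model rate M
    diverged_deme: tuple[int, float] | None = None  # (deme index, split time)
    ts_tv: float = 10.0
    infinite_sites: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_demes < 1 or len(self.sample_sizes) != self.n_demes:
            raise ValueError("sample_sizes must have one entry per deme")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.L < 1 or self.theta < 0:
            raise ValueError("L must be >= 1 and theta >= 0")
        if self.expansion is not None and (
            self.expansion[0] <= 0 or self.expansion[1] <= 0
        ):
            raise ValueError("expansion time and fold must be positive")
        if self.n_demes > 1 and self.migration is None and self.diverged_deme is None:
            raise ValueError("multiple demes need migration or a split time")
        if self.diverged_deme is not None:
            idx, t = self.diverged_deme
            if not (0 <= idx < self.n_demes) or t <= 0:
                raise ValueError("invalid diverged_deme")

    def fst_expected(self) -> float | None:
        """Island-model pairwise Phi_ST expectation among connected demes."""
        if self.migration is None or self.n_demes < 2:
            return None
        d = self.n_demes - (1 if self.diverged_deme is not None else 0)
        if d < 2:
            return None
        m = self.migration
        return (d - 1) / (m * d + d - 1)


@dataclass
class Branch:
    mask: int  # bitmask of descendant sample indices
    start: float  # child-side (more recent) end
    end: float  # parent-side end

    @property
    def length(self) -> float:
        return self.end - self.start


def simulate_genealogy(cfg: SimulationConfig, rng: np.random.Generator) -> list[Branch]:
    """Simulate one genealogy; returns every branch except above the root."""
    exp_time = cfg.expansion[0] if cfg.expansion else math.inf
    fold = cfg.expansion[1] if cfg.expansion else 1.0
    div_idx, split_time = (
        cfg.diverged_deme if cfg.diverged_deme is not None else (-1, math.inf)
    )
    mig = (cfg.migration or 0.0) / 2.0  # per-lineage rate

    # lineage -> (mask, deme, birth time)
    lineages: list[list] = []
    idx = 0
    for deme, size in enumerate(cfg.sample_sizes):
        for _ in range(size):
            lineages.append([1 << idx, deme, 0.0])
            idx += 1

    branches: list[Branch] = []
    t = 0.0
    boundaries = sorted(b for b in (exp_time, split_time) if math.isfinite(b))
    div_active = cfg.diverged_deme is not None  # isolated deme, pre-split
    panmictic = False  # post-split: everything collapsed into deme 0

    while len(lineages) > 1:
        size_scale = 1.0 / fold if t >= exp_time else 1.0
        per_deme: dict[int, list[int]] = {}
        for i, (_, deme, _) in enumerate(lineages):
            per_deme.setdefault(deme, []).append(i)
        coal_rates = {
            d: len(ix) * (len(ix) - 1) / 2.0 / size_scale
            for d, ix in per_deme.items()
        }
        # lineages in the isolated deme do not migrate before the split;
        # after the split everything lives in deme 0 and migration is moot
        if cfg.n_demes == 1 or panmictic:
            n_migratory = 0
        else:
            n_migratory = sum(
                len(ix)
                for d, ix in per_deme.items()
                if not (div_active and d == div_idx)
            )
        mig_rate = mig * n_migratory
        total = sum(coal_rates.values()) + mig_rate
        nxt = boundaries[0] if boundaries else math.inf
        if total == 0.0:
            if not math.isfinite(nxt):
                raise RuntimeError("genealogy cannot coalesce: no events possible")
            t = nxt
        else:
            dt = rng.exponential(1.0 / total)
            if t + dt >= nxt:
                t = nxt
            else:
                t += dt
                u = rng.uniform(0.0, total)
                acc = 0.0
                done = False
                for d, rate in coal_rates.items():
                    acc += rate
                    if u < acc:
                        ix = per_deme[d]
                        a, b = rng.choice(len(ix), size=2, replace=False)
                        ia, ib = ix[a], ix[b]
                        for i in (ia, ib):
                            branches.append(Branch(lineages[i][0], lineages[i][2], t))
                        new = [lineages[ia][0] | lineages[ib][0], d, t]
                        lineages = [
                            lin for i, lin in enumerate(lineages) if i not in (ia, ib)
                        ]
                        lineages.append(new)
                        done = True
                        break
                if not done:  # migration
                    movable = [
                        i
                        for i, (_, d, _) in enumerate(lineages)
                        if not (div_active and d == div_idx)
                    ]
                    i = movable[rng.integers(len(movable))]
                    cur = lineages[i][1]
                    others = [
                        d
                        for d in range(cfg.n_demes)
                        if d != cur and not (div_active and d == div_idx)
                    ]
                    lineages[i][1] = others[rng.integers(len(others))]
        if t == nxt and boundaries:
            boundaries.pop(0)
            if t == split_time:
                div_active = False
                panmictic = True
                for lin in lineages:
                    lin[1] = 0
    return branches


# ---------------------------------------------------------------------------
# mutation machinery


def drop_mutations(
    branches: Sequence[Branch],
    rng: np.random.Generator,
    theta: float | None = None,
    S: int | None = None,
) -> list[tuple[int, float]]:
    """Place mutations on branches; returns (branch index, time) pairs.

    Either Poisson with per-lineage rate ``theta/2`` (standard) or exactly
    ``S`` mutations multinomially by branch length (the fixed-S scheme used
    for Tajima's D null distributions).
    """
    lengths = np.array([b.length for b in branches], dtype=float)
    total = float(lengths.sum())
    if S is not None:
        if total <= 0:
            return []
        counts = rng.multinomial(S, lengths / total)
    elif theta is not None:
        counts = rng.poisson(theta / 2.0 * lengths)
    else:
        raise ValueError("need theta or S")
    out: list[tuple[int, float]] = []
    for bi, c in enumerate(counts):
        for _ in range(int(c)):
            out.append((bi, float(rng.uniform(branches[bi].start, branches[bi].end))))
    return out


def leaf_signatures(
    branches: Sequence[Branch], mutations: Sequence[tuple[int, float]], n: int
) -> list[int]:
    """Per-leaf bitmask over mutation indices (infinite-sites genotypes)."""
    sigs = [0] * n
    for mi, (bi, _) in enumerate(mutations):
        mask = branches[bi].mask
        bit = 1 << mi
        i = 0
        while mask:
            if mask & 1:
                sigs[i] |= bit
            mask >>= 1
            i += 1
    return sigs


def infinite_sites_stats(
    branches: Sequence[Branch], mutations: Sequence[tuple[int, float]], n: int
) -> tuple[int, float, int]:
    """(S, K, haplotype count) under infinite sites, without sequences."""
    S = len(mutations)
    pairs = n * (n - 1) / 2.0
    k = 0.0
    for bi, _ in mutations:
        i = branches[bi].mask.bit_count()
        k += i * (n - i)
    k /= pairs
    sigs = leaf_signatures(branches, mutations, n)
    return S, k, len(set(sigs))


def mismatch_counts_from_signatures(sigs: Sequence[int]) -> np.ndarray:
    """Histogram of pairwise difference counts (classes 0..max)."""
    n = len(sigs)
    diffs = [
        (sigs[i] ^ sigs[j]).bit_count() for i in range(n) for j in range(i + 1, n)
    ]
    out = np.zeros(max(diffs) + 1 if diffs else 1, dtype=float)
    for d in diffs:
        out[d] += 1
    return out


def sequences_from_genealogy(
    branches: Sequence[Branch],
    mutations: Sequence[tuple[int, float]],
    n: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Apply a finite-sites K2P-style mutation walk down the genealogy.

    Every mutation draws a site and substitution randomness once; all leaves
    below the branch see the same event. Per leaf, events on its root path
    are replayed oldest-first, so reverse and parallel hits behave correctly.
    """
    root = rng.integers(0, 4, size=cfg.L)
    p_ts = cfg.ts_tv / (cfg.ts_tv + 1.0)
    if cfg.infinite_sites:
        if len(mutations) > cfg.L:
            raise ValueError("more mutations than sites in infinite-sites mode")
        sites = rng.permutation(cfg.L)[: len(mutations)]
    else:
        sites = rng.integers(0, cfg.L, size=len(mutations))
    u_ts = rng.random(len(mutations))
    u_tv = rng.integers(0, 2, size=len(mutations))

    events = sorted(
        range(len(mutations)), key=lambda mi: mutations[mi][1], reverse=True
    )  # oldest first
    seqs: list[str] = []
    for leaf in range(n):
        bit = 1 << leaf
        seq = ["ACGT"[b] for b in root]
        for mi in events:
            bi, _ = mutations[mi]
            if branches[bi].mask & bit:
                s = int(sites[mi])
                base = seq[s]
                if u_ts[mi] < p_ts:
                    seq[s] = _TRANSITION[base]
                else:
                    seq[s] = _TRANSVERSIONS[base][int(u_tv[mi])]
        seqs.append("".join(seq))
    return seqs


# ---------------------------------------------------------------------------
# public API


def simulate_coalescent(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Alignment, PopulationMap, dict]:
    """Simulate one dataset; returns (Alignment, PopulationMap, truth)."""
    if rng is None:
        if cfg.seed is None:
            raise ValueError("a seed (or an explicit rng) is required")
        rng = np.random.default_rng(cfg.seed)
    n = sum(cfg.sample_sizes)
    branches = simulate_genealogy(cfg, rng)
    mutations = drop_mutations(branches, rng, theta=cfg.theta)
    seqs = sequences_from_genealogy(branches, mutations, n, cfg, rng)

    records = []
    assignments = {}
    i = 0
    for deme, size in enumerate(cfg.sample_sizes):
        pop = f"P{deme + 1}"
        for _ in range(size):
            i += 1
            sid = f"{pop}_{i:04d}"
            records.append((sid, seqs[i - 1]))
            assignments[sid] = pop
    truth = {
        "n_mutations": len(mutations),
        "tau_true": (cfg.theta * cfg.expansion[0]) if cfg.expansion else 0.0,
        "fst_expected": cfg.fst_expected(),
        "theta": cfg.theta,
    }
    return Alignment(tuple(records)), PopulationMap(assignments), truth


PAPER_LIKE = SimulationConfig(
    n_demes=7,
    sample_sizes=(46, 44, 47, 47, 48, 48, 46),
    L=674,
    theta=0.8,
    expansion=(2.5, 100.0),
    migration=20.0,
    diverged_deme=(6, 5.0),
    ts_tv=10.0,
)
"""Default study-shaped conditions: seven demes of 44-48 mtDNA sequences of
674 sites, low per-site diversity, a recent 100-fold sudden expansion
(tau_true = 2.0) producing a star-like genealogy around one high-frequency
haplotype, strong migration among six demes and one deme isolated for five
N-generations (strongly diverged, Phi_ST >> 0.4 against the rest)."""


def make_fixture(
    out_dir: str | Path, seed: int, style: str = "paper-like"
) -> tuple[Path, Path]:
    """Write a synthetic FASTA + population map emulating the study's shape.

    Returns (alignment path, population map path); a truth record is written
    alongside. Deterministic for a fixed seed.
    """
    if style != "paper-like":
        raise ValueError(f"unknown fixture style {style!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(**{**PAPER_LIKE.__dict__, "seed": seed})
    aln, pm, truth = simulate_coalescent(cfg)
    fasta = out / "synthetic_coi.fasta"
    popmap = out / "synthetic_popmap.csv"
    write_alignment(aln, fasta)
    with open(popmap, "w") as fh:
        fh.write("sample_id,population\n")
        for sid, pop in pm.assignments.items():
            fh.write(f"{sid},{pop}\n")
    with open(out / "synthetic_truth.csv", "w") as fh:
        fh.write("key,value\n")
        for k, v in truth.items():
            fh.write(f"{k},{v}\n")
    return fasta, popmap


# ---------------------------------------------------------------------------
# light-weight statistic engines used by neutrality tests and bootstraps


def single_population_stats(
    n: int,
    rng: np.random.Generator,
    theta: float | None = None,
    S: int | None = None,
    expansion: tuple[float, float] | None = None,
) -> tuple[int, float, int]:
    """One neutral-coalescent draw of (S, K, haplotype count) for one deme."""
    cfg = SimulationConfig(
        n_demes=1, sample_sizes=(n,), theta=theta or 0.0, expansion=expansion, seed=0
    )
    branches = simulate_genealogy(cfg, rng)
    muts = drop_mutations(branches, rng, theta=theta if S is None else None, S=S)
    return infinite_sites_stats(branches, muts, n)


def sudden_expansion_sample(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mismatch counts for one sample under the fitted expansion model.

    The stepwise model with present scaled size theta1 and ancient size
    theta0 maps onto the simulator as an expansion at coalescent time
    tau/theta1 with fold theta1/theta0 (theta0 = 0 becomes an effectively
    instantaneous ancestral coalescence).
    """
    if theta1 <= 0:
        raise ValueError("theta1 must be positive")
    if tau <= 0:
        # no expansion: equilibrium at the ancestral size
        cfg = SimulationConfig(
            n_demes=1, sample_sizes=(n,), theta=max(theta0, 1e-6), seed=0
        )
    else:
        fold = theta1 / max(theta0, 1e-9 * theta1, 1e-12)
        cfg = SimulationConfig(
            n_demes=1,
            sample_sizes=(n,),
            theta=theta1,
            expansion=(tau / theta1, fold),
            seed=0,
        )
    branches = simulate_genealogy(cfg, rng)
    muts = drop_mutations(branches, rng, theta=cfg.theta)
    sigs = leaf_signatures(branches, muts, n)
    return mismatch_counts_from_signatures(sigs)
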