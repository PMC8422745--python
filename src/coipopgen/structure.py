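"""AMOVA variance decomposition, pairwise Phi_ST and SAMOVA group search.

Phi-statistics are computed from pairwise sequence differences used as
squared Euclidean distances (the classic molecular-variance decomposition),
not from allele frequencies; tables elsewhere often label the same quantity
F_ST. Negative variance components are retained, so slightly negative
Phi_ST estimates are possible and meaningful (null differentiation).

Permutation p-values use the (1 + hits) / (1 + permutations) convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .haplotypes import included_sites
from .io import Alignment, PopulationMap


def pairwise_difference_matrix(aln: Alignment) -> np.ndarray:
    """Sample-by-sample count of differing included sites."""
    sites = included_sites(aln)
    arr = np.frombuffer(
        "".join(s for s in aln.sequences).encode(), dtype="S1"
    ).reshape(aln.n, aln.length)
    arr = arr[:, list(sites)]
    n = aln.n
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        out[i, i + 1:] = (arr[i + 1:] != arr[i]).sum(axis=1)
    return out + out.T


def _pair_sum(d: np.ndarray, idx: np.ndarray) -> float:
    """Sum of d over unordered pairs within idx."""
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum()) / 2.0


@dataclass
class AmovaResult:
    design: str  # "one-level" | "two-level"
    groups: tuple[tuple[str, ...], ...]
    df: dict[str, int]
    sums_of_squares: dict[str, float]
    variance_components: dict[str, float]
    percent_variation: dict[str, float]
    phi_ST: float
    phi_SC: float | None = None
    phi_CT: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        rows = []
        order = [k for k in ("among_groups", "among_populations",
                             "within_populations") if k in self.df]
        head = f"{'Source of variation':<32}{'d.f.':>6}{'SS':>12}{'Var':>10}{'%':>8}"
        rows.append("AMOVA (" + self.design + ")")
        rows.append("-" * len(head))
        rows.append(head)
        for k in order:
            rows.append(
                f"{k.replace('_', ' '):<32}{self.df[k]:>6}"
                f"{self.sums_of_squares[k]:>12.3f}"
                f"{self.variance_components[k]:>10.4f}"
                f"{self.percent_variation[k]:>8.2f}"
            )
        total_df = sum(self.df.values())
        total_ss = sum(self.sums_of_squares.values())
        rows.append(f"{'Total':<32}{total_df:>6}{total_ss:>12.3f}")
        rows.append("")
        for name, val in (("Phi_ST", self.phi_ST), ("Phi_SC", self.phi_SC),
                          ("Phi_CT", self.phi_CT)):
            if val is None:
                continue
            p = self.p_values.get(name)
            rows.append(f"{name} = {val:.4f}" + (f"  (p = {p:.4f})" if p is not None else ""))
        return "\n".join(rows)


def _amova_components(
    d: np.ndarray,
    pop_idx: list[np.ndarray],
    group_of_pop: list[int] | None,
) -> tuple[dict, dict, dict, float, float | None, float | None]:
    """Method-of-moments AMOVA from a squared-distance matrix.

    ``pop_idx`` holds sample indices per population; ``group_of_pop`` maps
    population position -> group id (None for the one-level design).
    """
    sizes = np.array([len(ix) for ix in pop_idx], dtype=float)
    if np.any(sizes < 2) and group_of_pop is None and len(pop_idx) > 0:
        small = [i for i, s in enumerate(sizes) if s < 2]
        if small:
            raise ValueError(f"population index {small[0]} has fewer than 2 samples")
    N = int(sizes.sum())
    P = len(pop_idx)
    all_idx = np.concatenate(pop_idx)
    ss_total = _pair_sum(d, all_idx) / N
    ss_wp = sum(_pair_sum(d, ix) / len(ix) for ix in pop_idx)

    if group_of_pop is None:
        df_ap, df_wp = P - 1, N - P
        ss_ap = ss_total - ss_wp
        sigma_c = ss_wp / df_wp
        n_prime = (N - float(np.sum(sizes**2)) / N) / (P - 1)
        sigma_a = (ss_ap / df_ap - sigma_c) / n_prime
        total = sigma_a + sigma_c
        phi_st = sigma_a / total if total != 0 else 0.0
        df = {"among_populations": df_ap, "within_populations": df_wp}
        ss = {"among_populations": ss_ap, "within_populations": ss_wp}
        var = {"among_populations": sigma_a, "within_populations": sigma_c}
        return df, ss, var, phi_st, None, None

    G = len(set(group_of_pop))
    group_pops: dict[int, list[int]] = {}
    for p, g in enumerate(group_of_pop):
        group_pops.setdefault(g, []).append(p)
    group_idx = {
        g: np.concatenate([pop_idx[p] for p in pops])
        for g, pops in group_pops.items()
    }
    ss_wg = sum(_pair_sum(d, ix) / len(ix) for ix in group_idx.values())
    ss_ag = ss_total - ss_wg
    ss_apwg = ss_wg - ss_wp
    df_ag, df_apwg, df_wp = G - 1, P - G, N - P
    sigma_c = ss_wp / df_wp

    group_sizes = {g: float(len(ix)) for g, ix in group_idx.items()}
    sum_n2_over_Ng = sum(
        sum(sizes[p] ** 2 for p in pops) / group_sizes[g]
        for g, pops in group_pops.items()
    )
    if df_apwg > 0:
        n1 = (N - sum_n2_over_Ng) / df_apwg
        sigma_b = (ss_apwg / df_apwg - sigma_c) / n1
    else:
        sigma_b = None  # every population its own group
    n2 = (sum_n2_over_Ng - float(np.sum(sizes**2)) / N) / df_ag
    n3 = (N - sum(v**2 for v in group_sizes.values()) / N) / df_ag
    sb = sigma_b if sigma_b is not None else 0.0
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sb) / n3
    total = sigma_a + sb + sigma_c
    phi_st = (sigma_a + sb) / total if total != 0 else 0.0
    phi_ct = sigma_a / total if total != 0 else 0.0
    phi_sc = sb / (sb + sigma_c) if sigma_b is not None and (sb + sigma_c) != 0 else None
    df = {"among_groups": df_ag, "among_populations": df_apwg,
          "within_populations": df_wp}
    ss = {"among_groups": ss_ag, "among_populations": ss_apwg,
          "within_populations": ss_wp}
    var = {"among_groups": sigma_a,
           "among_populations": sb if sigma_b is not None else float("nan"),
           "within_populations": sigma_c}
    return df, ss, var, phi_st, phi_sc, phi_ct


def _percent(var: dict[str, float]) -> dict[str, float]:
    vals = {k: (0.0 if math.isnan(v) else v) for k, v in var.items()}
    total = sum(vals.values())
    if total == 0:  # degenerate (e.g. monomorphic sample)
        return {k: (100.0 if k == "within_populations" else 0.0) for k in vals}
    return {k: 100.0 * v / total for k, v in vals.items()}


def amova(
    dists: np.ndarray,
    populations: list[str],
    groups: dict[str, int] | list[list[str]] | None = None,
    permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA on a sample-by-sample squared-distance matrix.

    ``populations[i]`` labels sample i. ``groups`` (optional) partitions the
    population labels for the two-level design. Permutation schemes: samples
    among populations (Phi_ST), populations among groups (Phi_CT), samples
    among populations within groups (Phi_SC).
    """
    populations = list(populations)
    labels = []
    for p in populations:
        if p not in labels:
            labels.append(p)
    pop_idx = [np.flatnonzero(np.array(populations) == p) for p in labels]
    for p, ix in zip(labels, pop_idx):
        if len(ix) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")

    group_of_pop = None
    group_tuple: tuple[tuple[str, ...], ...] = (tuple(labels),)
    if groups is not None:
        if isinstance(groups, dict):
            part: dict[int, list[str]] = {}
            for p, g in groups.items():
                part.setdefault(g, []).append(p)
            group_lists = [sorted(v) for _, v in sorted(part.items())]
        else:
            group_lists = [list(g) for g in groups]
        seen = [p for g in group_lists for p in g]
        if sorted(seen) != sorted(labels):
            raise ValueError("groups must partition the population labels")
        gmap = {p: gi for gi, g in enumerate(group_lists) for p in g}
        group_of_pop = [gmap[p] for p in labels]
        group_tuple = tuple(tuple(g) for g in group_lists)

    df, ss, var, phi_st, phi_sc, phi_ct = _amova_components(
        dists, pop_idx, group_of_pop
    )
    result = AmovaResult(
        design="one-level" if groups is None else "two-level",
        groups=group_tuple,
        df=df, sums_of_squares=ss, variance_components=var,
        percent_variation=_percent(var),
        phi_ST=phi_st, phi_SC=phi_sc, phi_CT=phi_ct,
    )
    if permutations > 0:
        if seed is None:
            raise ValueError("permutation tests require a seed")
        rng = np.random.default_rng(seed)
        result.p_values = _permutation_pvalues(
            dists, pop_idx, group_of_pop, result, permutations, rng
        )
    return result


def _permutation_pvalues(d, pop_idx, group_of_pop, obs: AmovaResult,
                         permutations: int, rng) -> dict[str, float]:
    sizes = [len(ix) for ix in pop_idx]
    all_idx = np.concatenate(pop_idx)
    hits_st = 0
    hits_sc = 0
    hits_ct = 0
    for _ in range(permutations):
        # Phi_ST: shuffle samples among populations
        perm = rng.permutation(all_idx)
        new_idx, off = [], 0
        for s in sizes:
            new_idx.append(perm[off:off + s])
            off += s
        st = _amova_components(d, new_idx, group_of_pop)[3]
        hits_st += st >= obs.phi_ST
        if group_of_pop is not None:
            # Phi_CT: shuffle whole populations among groups
            gperm = list(rng.permutation(group_of_pop))
            ct = _amova_components(d, pop_idx, gperm)[5]
            hits_ct += ct >= (obs.phi_CT or 0.0)
            # Phi_SC: shuffle samples among populations within groups
            if obs.phi_SC is not None:
                within_idx = [None] * len(pop_idx)
                for g in set(group_of_pop):
                    pops_g = [p for p, gg in enumerate(group_of_pop) if gg == g]
                    pool = rng.permutation(np.concatenate([pop_idx[p] for p in pops_g]))
                    off = 0
                    for p in pops_g:
                        within_idx[p] = pool[off:off + sizes[p]]
                        off += sizes[p]
                sc = _amova_components(d, within_idx, group_of_pop)[4]
                hits_sc += (sc if sc is not None else -np.inf) >= obs.phi_SC
    out = {"Phi_ST": (1 + hits_st) / (1 + permutations)}
    if group_of_pop is not None:
        out["Phi_CT"] = (1 + hits_ct) / (1 + permutations)
        if obs.phi_SC is not None:
            out["Phi_SC"] = (1 + hits_sc) / (1 + permutations)
    return out


def sequential_bonferroni(pvals: np.ndarray) -> np.ndarray:
    """Holm's sequential-Bonferroni adjustment (monotone, capped at 1).

    Off by default everywhere; raw p-values are what the tables report.
    """
    flat = np.asarray(pvals, dtype=float).ravel()
    mask = ~np.isnan(flat)
    p = flat[mask]
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    out = np.full(flat.shape, np.nan)
    out[mask] = adj
    return out.reshape(np.asarray(pvals).shape)


@dataclass
class PairwiseFstMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    p_values: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def adjusted_p_values(self) -> np.ndarray:
        """Sequential-Bonferroni p-values over the upper triangle."""
        k = len(self.labels)
        iu = np.triu_indices(k, 1)
        adj_flat = sequential_bonferroni(self.p_values[iu])
        adj = np.full((k, k), np.nan)
        adj[iu] = adj_flat
        adj.T[iu] = adj_flat
        return adj


def pairwise_fst(
    dists: np.ndarray,
    populations: list[str],
    permutations: int = 0,
    seed: int | None = None,
) -> PairwiseFstMatrix:
    """Phi_ST for every population pair (two-population one-level AMOVA)."""
    labels = []
    for p in populations:
        if p not in labels:
            labels.append(p)
    pops = np.array(populations)
    k = len(labels)
    values = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed) if seed is not None else None
    for i, j in itertools.combinations(range(k), 2):
        mask = (pops == labels[i]) | (pops == labels[j])
        idx = np.flatnonzero(mask)
        sub = dists[np.ix_(idx, idx)]
        sub_pops = list(pops[idx])
        res = amova(
            sub, sub_pops, permutations=permutations,
            seed=None if rng is None else int(rng.integers(2**31 - 1)),
        )
        values[i, j] = values[j, i] = res.phi_ST
        if permutations:
            pvals[i, j] = pvals[j, i] = res.p_values["Phi_ST"]
    return PairwiseFstMatrix(tuple(labels), values, pvals)


# ---------------------------------------------------------------------------
# SAMOVA-style group search


def _set_partitions_k(items: list[str], k: int):
    """All partitions of items into exactly k non-empty groups."""
    n = len(items)
    if not 1 <= k <= n:
        return
    # restricted growth strings with max value k-1
    def rec(i, assignment, used):
        if i == n:
            if used == k:
                groups = [[] for _ in range(k)]
                for item, g in zip(items, assignment):
                    groups[g].append(item)
                yield [tuple(g) for g in groups]
            return
        for g in range(min(used + 1, k)):
            assignment.append(g)
            yield from rec(i + 1, assignment, max(used, g + 1))
            assignment.pop()

    yield from rec(0, [], 0)


def samova(
    dists: np.ndarray,
    populations: list[str],
    K: int,
    permutations: int = 0,
    seed: int | None = None,
    n_starts: int = 100,
    anneal_steps: int = 2000,
    cooling: float = 0.995,
    force_annealing: bool = False,
    exhaustive_limit: int = 100_000,
) -> AmovaResult:
    """Find the K-group partition of populations maximizing Phi_CT.

    For small numbers of populations (number of K-partitions below
    ``exhaustive_limit``) the search enumerates all partitions; otherwise a
    simulated-annealing search with geometric cooling and multiple random
    starts is used. Geographic contiguity is NOT enforced. Returns the full
    two-level AMOVA for the best partition.
    """
    labels = []
    for p in populations:
        if p not in labels:
            labels.append(p)
    if not 2 <= K < len(labels):
        raise ValueError("K must satisfy 2 <= K < number of populations")
    pops_arr = np.array(populations)
    pop_idx = [np.flatnonzero(pops_arr == p) for p in labels]

    def phi_ct_of(assignment: list[int]) -> float:
        if len(set(assignment)) != K:
            return -np.inf
        ct = _amova_components(dists, pop_idx, assignment)[5]
        return ct if ct is not None else -np.inf

    def n_partitions() -> int:
        # Stirling number of the second kind S(n, K)
        n = len(labels)
        s = [[0] * (K + 1) for _ in range(n + 1)]
        s[0][0] = 1
        for i in range(1, n + 1):
            for j in range(1, K + 1):
                s[i][j] = j * s[i - 1][j] + s[i - 1][j - 1]
        return s[n][K]

    best_assignment: list[int] | None = None
    best_ct = -np.inf
    if not force_annealing and n_partitions() <= exhaustive_limit:
        for part in _set_partitions_k(labels, K):
            gmap = {p: gi for gi, g in enumerate(part) for p in g}
            assignment = [gmap[p] for p in labels]
            ct = phi_ct_of(assignment)
            if ct > best_ct:
                best_ct, best_assignment = ct, assignment
    else:
        if seed is None:
            raise ValueError("annealing search requires a seed")
        rng = np.random.default_rng(seed)
        for _ in range(n_starts):
            # random start with all K groups occupied
            assignment = list(rng.integers(0, K, size=len(labels)))
            for g in range(K):
                if g not in assignment:
                    assignment[int(rng.integers(len(labels)))] = g
            cur = phi_ct_of(assignment)
            temp = 1.0
            for _ in range(anneal_steps):
                cand = assignment.copy()
                cand[int(rng.integers(len(labels)))] = int(rng.integers(K))
                val = phi_ct_of(cand)
                if math.isfinite(val) and (
                    val > cur or rng.random() < math.exp((val - cur) / max(temp, 1e-12))
                ):
                    assignment, cur = cand, val
                if cur > best_ct:
                    best_ct, best_assignment = cur, assignment.copy()
                temp *= cooling
    if best_assignment is None:
        raise RuntimeError("no valid partition found")
    group_lists: list[list[str]] = [[] for _ in range(K)]
    for p, g in zip(labels, best_assignment):
        group_lists[g].append(p)
    group_lists = [g for g in group_lists if g]
    return amova(dists, populations, groups=group_lists,
                 permutations=permutations, seed=seed)
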