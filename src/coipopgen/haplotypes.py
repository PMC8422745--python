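"""Haplotype collapsing, frequency tables and polymorphic-site summaries.

Missing data (``-`` or ``N``) is handled by complete deletion: any column
containing a missing state in ANY sequence is excluded before haplotypes are
collapsed and before S, K and pi are computed. The number of excluded columns
is always reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import MISSING, Alignment, PopulationMap


def included_sites(aln: Alignment) -> tuple[int, ...]:
    """Indices of columns free of missing data in every sequence."""
    seqs = aln.sequences
    return tuple(
        j for j in range(aln.length) if all(s[j] not in MISSING for s in seqs)
    )


def restrict(seq: str, sites: Sequence[int]) -> str:
    return "".join(seq[j] for j in sites)


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with per-population counts.

    Haplotype ids are ``Hap_1, Hap_2, ...`` in descending order of total
    count (ties broken by first occurrence in the alignment), so the modal
    haplotype is always ``Hap_1``.
    """

    haplotypes: tuple[tuple[str, str], ...]  # (haplotype_id, sequence)
    counts: Mapping[str, Mapping[str, int]]  # hap_id -> pop -> count
    excluded_sites: int = 0

    @property
    def total_n(self) -> int:
        return sum(sum(p.values()) for p in self.counts.values())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def populations(self) -> tuple[str, ...]:
        pops: list[str] = []
        for per_pop in self.counts.values():
            for p in per_pop:
                if p not in pops:
                    pops.append(p)
        return tuple(pops)

    def total_count(self, hap_id: str) -> int:
        return sum(self.counts[hap_id].values())

    def population_counts(self, population: str) -> dict[str, int]:
        """hap_id -> count within one population (zero counts dropped)."""
        out = {}
        for hap_id, per_pop in self.counts.items():
            c = per_pop.get(population, 0)
            if c:
                out[hap_id] = c
        return out

    def singletons(self) -> tuple[str, ...]:
        return tuple(h for h, _ in self.haplotypes if self.total_count(h) == 1)

    def sequence_of(self, hap_id: str) -> str:
        for h, seq in self.haplotypes:
            if h == hap_id:
                return seq
        raise KeyError(hap_id)

    def to_frame(self) -> pd.DataFrame:
        pops = self.populations
        rows = []
        for hap_id, seq in self.haplotypes:
            row: dict[str, object] = {"haplotype": hap_id}
            for p in pops:
                row[p] = self.counts[hap_id].get(p, 0)
            row["total"] = self.total_count(hap_id)
            row["sequence"] = seq
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SiteSummary:
    S: int
    parsimony_informative: int
    singleton_sites: int
    excluded_sites: int


def collapse_haplotypes(aln: Alignment, pm: PopulationMap) -> HaplotypeTable:
    """Collapse identical sequences (on included sites) into haplotypes."""
    pm.require_complete(aln)
    sites = included_sites(aln)
    excluded = aln.length - len(sites)

    order: list[str] = []  # restricted sequences in first-occurrence order
    totals: Counter[str] = Counter()
    per_pop: dict[str, Counter[str]] = {}
    for sid, seq in aln.records:
        key = restrict(seq, sites)
        if key not in totals:
            order.append(key)
        totals[key] += 1
        per_pop.setdefault(key, Counter())[pm.assignments[sid]] += 1

    ranked = sorted(order, key=lambda k: (-totals[k], order.index(k)))
    haplotypes = tuple((f"Hap_{i + 1}", key) for i, key in enumerate(ranked))
    counts = {
        hap_id: dict(per_pop[key]) for (hap_id, key) in haplotypes
    }
    return HaplotypeTable(haplotypes, counts, excluded)


def expand_to_alignment(table: HaplotypeTable) -> tuple[Alignment, PopulationMap]:
    """Inverse input mode: rebuild a per-individual alignment from a table.

    Lets a published haplotype-by-population count table plus the haplotype
    sequences drive the full pipeline without per-individual data.
    """
    records: list[tuple[str, str]] = []
    assignments: dict[str, str] = {}
    i = 0
    for hap_id, seq in table.haplotypes:
        for pop in table.populations:
            for _ in range(table.counts[hap_id].get(pop, 0)):
                i += 1
                sid = f"{pop}_{i:04d}"
                records.append((sid, seq))
                assignments[sid] = pop
    return Alignment(tuple(records)), PopulationMap(assignments)


def read_haplotype_table(path: str | Path) -> HaplotypeTable:
    """Read a CSV in the layout written by :meth:`HaplotypeTable.to_csv`."""
    df = pd.read_csv(path)
    pops = [c for c in df.columns if c not in ("haplotype", "total", "sequence")]
    haps = tuple((str(r["haplotype"]), str(r["sequence"])) for _, r in df.iterrows())
    counts = {
        str(r["haplotype"]): {p: int(r[p]) for p in pops if int(r[p]) > 0}
        for _, r in df.iterrows()
    }
    return HaplotypeTable(haps, counts)


def site_summary(aln: Alignment) -> SiteSummary:
    """Count segregating, parsimony-informative and singleton sites.

    A site segregates if >= 2 distinct non-missing bases occur; it is
    parsimony-informative if >= 2 bases each occur >= 2 times. Columns with
    any missing data are excluded entirely (complete deletion).
    """
    sites = included_sites(aln)
    seqs = aln.sequences
    s = informative = 0
    for j in sites:
        cnt = Counter(seq[j] for seq in seqs)
        if len(cnt) >= 2:
            s += 1
            if sum(1 for v in cnt.values() if v >= 2) >= 2:
                informative += 1
    return SiteSummary(
        S=s,
        parsimony_informative=informative,
        singleton_sites=s - informative,
        excluded_sites=aln.length - len(sites),
    )


def shared_and_unique(table: HaplotypeTable) -> pd.DataFrame:
    """Per-population haplotype counts h and unique haplotypes h'.

    Returns a frame with one row per population (columns ``population``,
    ``n``, ``h``, ``h_prime``) plus attrs ``shared`` (haplotype ids present
    in >= 2 populations) and ``widespread`` (present in all populations).
    """
    pops = table.populations
    presence = {
        hap_id: [p for p in pops if table.counts[hap_id].get(p, 0) > 0]
        for hap_id, _ in table.haplotypes
    }
    rows = []
    for p in pops:
        here = [h for h, where in presence.items() if p in where]
        rows.append(
            {
                "population": p,
                "n": sum(table.counts[h].get(p, 0) for h in here),
                "h": len(here),
                "h_prime": sum(1 for h in here if presence[h] == [p]),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["shared"] = tuple(h for h, w in presence.items() if len(w) >= 2)
    df.attrs["widespread"] = tuple(
        h for h, w in presence.items() if len(w) == len(pops)
    )
    return df
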