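"""Reading and writing of on-disk artifacts.

Alignments come in as FASTA (all sequences the same length — the input is
assumed pre-aligned), sample-to-population maps as delimited text, and the
result side writes newick trees, GraphML haplotype networks and CSV tables.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN-")
MISSING = frozenset("N-")


class AlignmentError(ValueError):
    """Sequences do not form a valid equal-length alignment."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Alignment:
    """An equal-length nucleotide alignment with ordered, unique sample ids.

    The alphabet is restricted to ``{A, C, G, T, N, -}`` after uppercasing;
    ``N`` and ``-`` are both treated as missing data downstream.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no sequences")
        length = len(self.records[0][1])
        seen: set[str] = set()
        for sid, seq in self.records:
            if sid in seen:
                raise AlignmentError(f"duplicate sample id {sid!r}")
            seen.add(sid)
            if len(seq) != length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(seq)}, expected {length}"
                )
            for col, ch in enumerate(seq):
                if ch not in VALID_BASES:
                    raise FormatError(
                        f"illegal character {ch!r} in record {sid!r} at column {col + 1}"
                    )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(tuple((sid, seq.upper()) for sid, seq in pairs))

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        wanted = set(sample_ids)
        return Alignment(tuple(r for r in self.records if r[0] in wanted))


@dataclass(frozen=True)
class PopulationMap:
    """sample_id -> population label, with optional deme coordinates."""

    assignments: Mapping[str, str]
    coordinates: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, pop in self.assignments.items():
            if not pop:
                raise FormatError(f"empty population label for sample {sid!r}")

    @property
    def populations(self) -> tuple[str, ...]:
        """Population labels in first-appearance order."""
        out: list[str] = []
        for pop in self.assignments.values():
            if pop not in out:
                out.append(pop)
        return tuple(out)

    def samples_in(self, population: str) -> tuple[str, ...]:
        return tuple(s for s, p in self.assignments.items() if p == population)

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for pop in self.assignments.values():
            out[pop] = out.get(pop, 0) + 1
        return out

    def require_complete(self, aln: Alignment) -> None:
        missing = [s for s in aln.sample_ids if s not in self.assignments]
        if missing:
            raise FormatError(
                f"{len(missing)} aligned samples lack a population assignment "
                f"(first: {missing[0]!r})"
            )


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment; case-insensitive, order-preserving."""
    path = Path(path)
    try:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    except OSError as exc:
        raise FormatError(f"cannot read alignment {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return Alignment(tuple(records))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n{seq}\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a sample->population map.

    Accepts CSV with a ``sample_id,population`` header (extra ``latitude`` /
    ``longitude`` columns allowed) or a headerless two-column whitespace file.
    """
    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0] if text.strip() else ""
    assignments: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    if "," in first:
        reader = csv.DictReader(_stdio.StringIO(text))
        fields = reader.fieldnames or []
        if "sample_id" not in fields or "population" not in fields:
            raise FormatError(
                f"{path}: expected header with sample_id and population columns, got {fields}"
            )
        for row in reader:
            sid, pop = row["sample_id"].strip(), row["population"].strip()
            if sid in assignments:
                raise FormatError(f"{path}: duplicate sample_id {sid!r}")
            assignments[sid] = pop
            if row.get("latitude") and row.get("longitude"):
                coords[pop] = (float(row["latitude"]), float(row["longitude"]))
    else:
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            sid, pop = parts
            if sid in assignments:
                raise FormatError(f"{path}: duplicate sample_id {sid!r}")
            assignments[sid] = pop
    if not assignments:
        raise FormatError(f"{path}: empty population map")
    return PopulationMap(assignments, coords)


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (distances_trees.Tree) as newick with branch lengths."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write a haplotype network as GraphML.

    Node attributes carry total frequency and per-population composition
    (flattened to ``pop:<label>`` attributes, since GraphML values are scalar).
    """
    g = nx.Graph()
    for node, data in net.nodes(data=True):
        attrs = {k: v for k, v in data.items() if not isinstance(v, dict)}
        for pop, cnt in data.get("populations", {}).items():
            attrs[f"pop:{pop}"] = int(cnt)
        g.add_node(node, **attrs)
    for u, v, data in net.edges(data=True):
        g.add_edge(u, v, **data)
    try:
        nx.write_graphml(g, str(path))
    except OSError as exc:
        raise FormatError(f"cannot write network {path}: {exc}") from exc


def write_results_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                        float_format: str = "%.4f") -> None:
    """Write a list of dict rows as CSV with fixed column order.

    Column order is taken from the first row. Floats are formatted with
    ``float_format`` (default 4 decimals, matching the diversity/Phi tables;
    neutrality statistics are written with 3 decimals by the pipeline).
    """
    if not rows:
        raise ValueError("no rows to write")
    cols = list(rows[0].keys())
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for row in rows:
                out = []
                for c in cols:
                    v = row[c]
                    if isinstance(v, float):
                        out.append(float_format % v)
                    else:
                        out.append(v)
                writer.writerow(out)
    except OSError as exc:
        raise FormatError(f"cannot write table {path}: {exc}") from exc
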