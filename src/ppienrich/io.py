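"""Readers and writers for the external formats the tool touches.

Everything downstream consumes only the domain objects built here:
gene-set collections (GMT), query gene lists, STRING-style protein
interaction edge lists, FASTA sequences and protein embedding tables.
Identifier matching across all inputs is case-sensitive and exact; no
ID-mapping layer is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "QueryList",
    "EdgeList",
    "EmbeddingTable",
    "read_gmt",
    "write_gmt",
    "read_query",
    "read_string_edges",
    "read_fasta",
    "read_embedding_table",
    "write_embedding_table",
    "write_results",
    "RESULT_COLUMNS",
]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GeneSet:
    pathway_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.pathway_id!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered pathway collection, e.g. one GMT database."""

    name: str
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        ids = [s.pathway_id for s in self.sets]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass(frozen=True)
class QueryList:
    """An ordered, duplicate-free list of query gene/protein identifiers."""

    identifiers: tuple[str, ...]
    label: str = "query"

    def __post_init__(self) -> None:
        if not self.identifiers:
            raise ValueError("empty query")
        if len(set(self.identifiers)) != len(self.identifiers):
            raise ValueError("query contains duplicates")

    def __len__(self) -> int:
        return len(self.identifiers)


@dataclass
class EdgeList:
    """Undirected PPI edges with STRING-style combined scores in [0, 1000].

    Symmetric duplicates are merged (keeping the max score) and self-loops
    are forbidden, so the adjacency relation is symmetric and irreflexive.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float] = {}
        for a, b, s in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            key = (a, b) if a <= b else (b, a)
            canon[key] = max(canon.get(key, -np.inf), float(s))
        self.edges = [(a, b, s) for (a, b), s in canon.items()]

    def __len__(self) -> int:
        return len(self.edges)

    def pair_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.edges}

    def node_ids(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out


class EmbeddingTable:
    """Mapping from protein identifier to a fixed-length embedding vector hP."""

    def __init__(self, ids: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if len(ids) != matrix.shape[0]:
            raise ValueError("ids / matrix row mismatch")
        if matrix.shape[1] < 3:
            raise ValueError(
                "embedding dimension must be >= 3 (Pearson correlation is "
                "degenerate below that)"
            )
        if not np.all(np.isfinite(matrix)):
            raise ValueError("non-finite embedding values")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate identifiers in embedding table")
        self.ids: tuple[str, ...] = tuple(ids)
        self.matrix = matrix
        self._index = {p: i for i, p in enumerate(self.ids)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[float]]) -> "EmbeddingTable":
        ids = list(mapping)
        return cls(ids, np.array([list(mapping[i]) for i in ids], dtype=float))

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._index

    def __getitem__(self, identifier: str) -> np.ndarray:
        return self.matrix[self._index[identifier]]

    def index_of(self, identifier: str) -> int:
        return self._index[identifier]


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file (tab-separated: id, description, members)."""
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            pathway_id, description = fields[0], fields[1]
            if pathway_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pathway_id!r}")
            seen.add(pathway_id)
            members: list[str] = []
            for m in fields[2:]:
                m = m.strip()
                if not m:
                    continue
                if m in members:
                    logger.warning(
                        "%s:%d: duplicate member %r in %s dropped", path, lineno, m, pathway_id
                    )
                    continue
                members.append(m)
            sets.append(GeneSet(pathway_id, description, tuple(members)))
    return GeneSetCollection(name or path.stem, tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join((s.pathway_id, s.description, *s.members)) + "\n")


def read_query(path: str | Path, label: str | None = None) -> QueryList:
    """Read a query list: one identifier per line, '#' lines are comments."""
    path = Path(path)
    identifiers: list[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token in identifiers:
                logger.warning("%s: duplicate identifier %r dropped", path, token)
                continue
            identifiers.append(token)
    if not identifiers:
        raise ParseError(f"{path}: empty query")
    return QueryList(tuple(identifiers), label or path.stem)


def read_string_edges(path: str | Path, min_score: float = 0.0) -> EdgeList:
    """Read a STRING protein.links-dialect edge file.

    Whitespace-separated ``protein1 protein2 combined_score`` rows; an
    optional header starting with ``protein1`` is skipped.  Edges with
    score < *min_score* and self-loops are dropped; symmetric duplicates
    are merged keeping the larger score.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and parts[0] == "protein1":
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 whitespace-separated fields")
            a, b = parts[0], parts[1]
            try:
                score = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from None
            if a == b:
                logger.warning("%s:%d: self-loop on %r dropped", path, lineno, a)
                continue
            if score < min_score:
                continue
            edges.append((a, b, score))
    return EdgeList(edges)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA sequences; non-canonical residues are mapped to X with a warning."""
    path = Path(path)
    sequences: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    canonical = set(CANONICAL_AA) | {"X"}

    def flush() -> None:
        if current is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {current!r}")
        bad = sorted(set(seq) - canonical)
        if bad:
            logger.warning("%s: %r contains non-canonical residues %s -> X", path, current, bad)
            seq = "".join(c if c in canonical else "X" for c in seq)
        sequences[current] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                ident = line[1:].split()[0] if line[1:].split() else ""
                if not ident:
                    raise ParseError(f"{path}: empty FASTA header")
                if ident in sequences:
                    raise ParseError(f"{path}: duplicate identifier {ident!r}")
                current = ident
                chunks = []
            else:
                if current is None:
                    raise ParseError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not sequences:
        raise ParseError(f"{path}: no records")
    return sequences


def read_embedding_table(path: str | Path) -> EmbeddingTable:
    """Read a TSV embedding table: identifier column followed by d numeric columns."""
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ParseError(f"{path}:{lineno}: ragged row ({len(parts)} != {width} fields)")
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric embedding value") from None
            ids.append(parts[0])
    if not rows:
        raise ParseError(f"{path}: empty table")
    return EmbeddingTable(ids, np.asarray(rows))


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    """Write a TSV embedding table with full round-trip precision."""
    with open(path, "w") as fh:
        for i, ident in enumerate(table.ids):
            values = "\t".join(repr(float(v)) for v in table.matrix[i])
            fh.write(f"{ident}\t{values}\n")


RESULT_COLUMNS = [
    "pathway_id",
    "pathway_size",
    "overlap",
    "coverage",
    "interactions",
    "score",
    "pvalue",
    "bh",
]


def write_results(results: Sequence, path: str | Path) -> None:
    """Write enrichment results as a sorted TSV.

    Rows are ordered by ascending BH-adjusted p, then raw p, then
    descending score, with pathway_id as the deterministic tie-break.
    """
    if not results:
        raise ValueError("no results to write")
    df = pd.DataFrame([{c: getattr(r, c) for c in RESULT_COLUMNS} for r in results])
    df = df.sort_values(
        by=["bh", "pvalue", "score", "pathway_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    df.to_csv(path, sep="\t", index=False)
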