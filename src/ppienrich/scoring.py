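"""Embedding-correlation enrichment scoring.

The association between a query gene list and a pathway is measured on
the proteins' embedding vectors: a Pearson correlation matrix C between
every query protein and every pathway protein is filtered (entries must
exceed a strict threshold, default 0.9, others are zeroed), exact gene
overlaps are masked so a shared gene contributes a single entry of
exactly 1 while the rest of its column is zeroed, and the matrix is
decomposed into an overlap part (binary) and an interaction part.  The
weighted enrichment score is

    WES = mean_k max_l ( C_interaction + beta * C_overlap )_{k,l}

i.e. the mean over query proteins of each protein's best weighted match
in the pathway.  beta = 1 gives the plain enrichment score ES; larger
beta progressively favours pathways sharing genes with the query over
pathways that are merely strongly interaction-linked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import EdgeList, EmbeddingTable, GeneSetCollection, QueryList
from .utils import standardize_rows

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringConfig",
    "SetEncoding",
    "ScoreBreakdown",
    "EnrichmentResult",
    "pearson",
    "correlation_matrix",
    "apply_filter",
    "apply_overlap_mask",
    "decompose",
    "weighted_score",
    "count_interactions",
    "count_correlation_entries",
    "score_pair",
    "enrich",
]


@dataclass(frozen=True)
class ScoringConfig:
    """beta weights exact gene overlaps relative to interaction-driven
    correlation entries; corr_threshold is the strict filtration cutoff."""

    beta: float = 10.0
    corr_threshold: float = 0.9
    missing_as_zero: bool = False

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SetEncoding:
    """Ordered stack of embedding vectors for a gene list.

    identifiers are the genes retained (present in the embedding table);
    dropped records the ones without an embedding.
    """

    identifiers: tuple[str, ...]
    matrix: np.ndarray  # (len(identifiers), d)
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.identifiers):
            raise ValueError("row count must equal number of identifiers")
        if len(self.identifiers) and self.matrix.shape[1] < 3:
            raise ValueError("embedding dimension must be >= 3")

    @classmethod
    def from_table(
        cls, identifiers: Sequence[str], table: EmbeddingTable, warn_label: str = "set"
    ) -> "SetEncoding":
        kept = [i for i in identifiers if i in table]
        dropped = tuple(i for i in identifiers if i not in table)
        if dropped:
            logger.warning(
                "%s: %d identifier(s) missing from the embedding table: %s",
                warn_label,
                len(dropped),
                list(dropped)[:10],
            )
        matrix = (
            np.array([table[i] for i in kept]) if kept else np.empty((0, table.dim))
        )
        return cls(tuple(kept), matrix, dropped)

    def __len__(self) -> int:
        return len(self.identifiers)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Filtered/masked correlation matrix and its decomposition."""

    C: np.ndarray  # filtered + overlap-masked, N x M
    C_overlap: np.ndarray  # binary
    C_interaction: np.ndarray
    maxC: np.ndarray  # length N (row maxima of C_interaction + beta*C_overlap)
    score: float
    overlap_pairs: tuple[tuple[int, int], ...]
    beta: float
    empty: bool = False


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_size: int
    overlap: int
    coverage: float
    interactions: int
    score: float
    pvalue: float = float("nan")
    bh: float = float("nan")
    skipped: bool = False


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation over vector coordinates; 0 if either vector has
    zero variance (degenerate-embedding convention)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("pearson needs two equal-length 1-D vectors")
    if u.size < 3:
        raise ValueError("pearson needs dimension >= 3")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


def correlation_matrix(query: SetEncoding, pathway: SetEncoding) -> np.ndarray:
    """Raw N x M Pearson matrix between query and pathway embeddings."""
    if len(query) and len(pathway) and query.matrix.shape[1] != pathway.matrix.shape[1]:
        raise ValueError("query and pathway embeddings have different dimensions")
    zq = standardize_rows(query.matrix) if len(query) else query.matrix
    zp = standardize_rows(pathway.matrix) if len(pathway) else pathway.matrix
    return np.clip(zq @ zp.T, -1.0, 1.0)


def apply_filter(raw: np.ndarray, corr_threshold: float = 0.9) -> np.ndarray:
    """Zero every entry not strictly above the threshold (an entry exactly
    at the cutoff is removed)."""
    if not 0 < corr_threshold < 1:
        raise ValueError("corr_threshold must be in (0, 1)")
    return np.where(raw > corr_threshold, raw, 0.0)


def apply_overlap_mask(
    filtered: np.ndarray, query_ids: Sequence[str], pathway_ids: Sequence[str]
) -> tuple[np.ndarray, tuple[tuple[int, int], ...]]:
    """Mask exact gene overlaps.

    A shared identifier (query row k, pathway column l) marks the two
    genes as the same protein: the entry (k, l) is set to exactly 1 and
    every other entry of column l is zeroed, so an overlapping gene
    cannot also contribute interaction signal.  Overlap is decided by
    identifier equality, not by a floating-point correlation of 1.
    """
    masked = filtered.copy()
    q_index = {g: k for k, g in enumerate(query_ids)}
    pairs: list[tuple[int, int]] = []
    for l, g in enumerate(pathway_ids):
        k = q_index.get(g)
        if k is None:
            continue
        masked[:, l] = 0.0
        masked[k, l] = 1.0
        pairs.append((k, l))
    return masked, tuple(pairs)


def decompose(
    masked: np.ndarray, overlap_pairs: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Split the masked matrix into a binary overlap part and the residual
    interaction part; C_overlap + C_interaction reconstructs the input."""
    C_overlap = np.zeros_like(masked)
    for k, l in overlap_pairs:
        C_overlap[k, l] = 1.0
    return C_overlap, masked - C_overlap


def weighted_score(
    C_overlap: np.ndarray, C_interaction: np.ndarray, beta: float = 10.0
) -> tuple[np.ndarray, float]:
    """Row maxima of C_interaction + beta*C_overlap and their mean (WES)."""
    if C_overlap.shape != C_interaction.shape:
        raise ValueError("shape mismatch between overlap and interaction parts")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    n, m = C_overlap.shape
    if n == 0 or m == 0:
        return np.zeros(n), 0.0
    weighted = C_interaction + beta * C_overlap
    maxC = weighted.max(axis=1)
    return maxC, float(maxC.mean())


def score_pair(
    query: SetEncoding, pathway: SetEncoding, config: ScoringConfig
) -> ScoreBreakdown:
    """Full scoring pipeline for one (query, pathway) pair:
    correlation -> filtration -> overlap masking -> decomposition -> WES."""
    raw = correlation_matrix(query, pathway)
    filtered = apply_filter(raw, config.corr_threshold)
    masked, pairs = apply_overlap_mask(filtered, query.identifiers, pathway.identifiers)
    C_overlap, C_interaction = decompose(masked, pairs)
    maxC, score = weighted_score(C_overlap, C_interaction, config.beta)
    empty = len(query) == 0 or len(pathway) == 0
    return ScoreBreakdown(masked, C_overlap, C_interaction, maxC, score, pairs, config.beta, empty)


def count_interactions(
    query_ids: Sequence[str], pathway_ids: Sequence[str], edges: EdgeList
) -> int:
    """Number of PPI edges with one endpoint in the query and the other in
    the pathway, each unordered pair counted once."""
    q = set(query_ids)
    p = set(pathway_ids)
    count = 0
    for a, b, _ in edges.edges:
        if (a in q and b in p) or (b in q and a in p):
            count += 1
    return count


def count_correlation_entries(breakdown: ScoreBreakdown) -> int:
    """Alternative interaction counter: supra-threshold correlation entries
    (nonzeros of the interaction part)."""
    return int(np.count_nonzero(breakdown.C_interaction))


def enrich(
    query: QueryList,
    collection: GeneSetCollection,
    table: EmbeddingTable,
    config: ScoringConfig | None = None,
    edges: EdgeList | None = None,
) -> list[EnrichmentResult]:
    """Score the query against every pathway of the collection.

    Pathways with no encodable member are emitted with score 0 and the
    skipped flag (they carry no statistical meaning and are excluded from
    the BH family downstream).  p-values are filled by the significance
    module.
    """
    config = config or ScoringConfig()
    q_enc = SetEncoding.from_table(query.identifiers, table, warn_label=query.label)
    if len(q_enc) == 0:
        raise ValueError("no query identifiers found in the embedding table")
    if config.missing_as_zero and q_enc.dropped:
        zeros = np.zeros((len(q_enc.dropped), table.dim))
        q_enc = SetEncoding(
            q_enc.identifiers + q_enc.dropped,
            np.vstack([q_enc.matrix, zeros]),
            (),
        )
    results: list[EnrichmentResult] = []
    for gene_set in collection:
        p_enc = SetEncoding.from_table(gene_set.members, table, warn_label=gene_set.pathway_id)
        n_interactions = (
            count_interactions(query.identifiers, gene_set.members, edges) if edges else 0
        )
        if len(p_enc) == 0:
            results.append(
                EnrichmentResult(
                    gene_set.pathway_id, 0, 0, 0.0, n_interactions, 0.0, skipped=True
                )
            )
            continue
        breakdown = score_pair(q_enc, p_enc, config)
        overlap = len(breakdown.overlap_pairs)
        results.append(
            EnrichmentResult(
                gene_set.pathway_id,
                len(p_enc),
                overlap,
                overlap / len(p_enc),
                n_interactions,
                breakdown.score,
            )
        )
    return results
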