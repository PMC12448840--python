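"""Permutation null distributions, empirical p-values and BH/FDR control.

Random gene lists of the same size as the (encoded) query are sampled
uniformly without replacement from the universe of proteins with an
embedding; the same lists are reused across every pathway, and each
pathway's observed score is compared with its own null.  The estimator
p = (b + 1) / n, where b counts null scores >= the observed score, never
returns 0 and attains its minimum 1/n — 0.00001 at the production
default of 100 000 permutations.  p-values are then adjusted with the
Benjamini–Hochberg step-up procedure over all non-skipped pathways of
the collection.

Null scores depend on beta and the correlation threshold, so nulls must
be recomputed whenever the scoring configuration changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import EmbeddingTable, GeneSetCollection
from .scoring import EnrichmentResult, ScoringConfig, SetEncoding
from .utils import standardize_rows

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "NullDistribution",
    "sample_null_queries",
    "empirical_pvalue",
    "bh_adjust",
    "batch_scores",
    "assess",
]


@dataclass(frozen=True)
class NullConfig:
    """n_permutations defaults to 500 for test-scale runs; production runs
    use 100 000 (the run time scales as permutations x pathways)."""

    n_permutations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class NullDistribution:
    pathway_id: str
    scores: np.ndarray
    beta: float
    corr_threshold: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite null scores")
        if np.any(self.scores < 0) or np.any(self.scores > self.beta):
            raise ValueError("null scores outside [0, beta]")


def sample_null_queries(
    universe: Sequence[str], size: int, n: int, seed: int
) -> np.ndarray:
    """n uniform without-replacement samples of `size` universe indices.

    Returns an (n, size) integer index array into `universe`; the same
    array must be reused for every pathway of a run.
    """
    if size > len(universe):
        raise ValueError(f"query size {size} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    m = len(universe)
    out = np.empty((n, size), dtype=int)
    for i in range(n):
        out[i] = rng.choice(m, size=size, replace=False)
    return out


def empirical_pvalue(observed: float, null_scores: np.ndarray) -> float:
    """p = min(1, (b + 1) / n) with b = #{null >= observed}; the minimal
    attainable value is 1/n and 0 is never returned."""
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise ValueError("empty null distribution")
    b = int(np.count_nonzero(null_scores >= observed))
    return min(1.0, (b + 1) / null_scores.size)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def batch_scores(
    Z: np.ndarray,
    query_idx: np.ndarray,
    pathway_idx: np.ndarray,
    config: ScoringConfig,
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorised WES for many queries against one pathway.

    Z is the row-standardized embedding matrix of the universe, query_idx
    an (n, N) index array and pathway_idx the (M,) pathway member
    indices.  Semantics match scoring.score_pair: strict filtration,
    identifier-equality overlap masking (index equality here) and row-max
    averaging of the beta-weighted matrix.
    """
    n, N = query_idx.shape
    Zp = Z[pathway_idx]
    out = np.empty(n)
    for start in range(0, n, chunk):
        idx = query_idx[start : start + chunk]
        C = np.clip(Z[idx] @ Zp.T, -1.0, 1.0)  # (c, N, M)
        C = np.where(C > config.corr_threshold, C, 0.0)
        overlap = idx[:, :, None] == pathway_idx[None, None, :]
        col_has_overlap = overlap.any(axis=1, keepdims=True)
        C = np.where(col_has_overlap & ~overlap, 0.0, C)
        C = np.where(overlap, config.beta, C)
        out[start : start + chunk] = C.max(axis=2).mean(axis=1)
    return out


def assess(
    results: list[EnrichmentResult],
    query,
    collection: GeneSetCollection,
    table: EmbeddingTable,
    config: ScoringConfig | None = None,
    null_config: NullConfig | None = None,
) -> list[EnrichmentResult]:
    """Fill pvalue and bh on results produced by scoring.enrich.

    The null universe is every protein with an embedding; the null query
    size is the number of query genes actually scored (post-coverage).
    The same sampled lists are reused for every pathway.  The BH family
    is all non-skipped pathways of the collection.  Results whose score
    cannot be reproduced under *config* (e.g. a beta mismatch between
    enrich and assess) raise an error.
    """
    config = config or ScoringConfig()
    null_config = null_config or NullConfig()
    by_id = {s.pathway_id: s for s in collection}
    unknown = [r.pathway_id for r in results if r.pathway_id not in by_id]
    if unknown:
        raise ValueError(f"results reference pathways absent from the collection: {unknown}")

    live = [r for r in results if not r.skipped]
    if not live:
        return results

    q_enc = SetEncoding.from_table(query.identifiers, table, warn_label="query")
    if len(q_enc) == 0:
        raise ValueError("no query identifiers found in the embedding table")
    Z = standardize_rows(table.matrix)
    q_idx = np.array([[table.index_of(g) for g in q_enc.identifiers]])
    null_idx = sample_null_queries(
        table.ids, len(q_enc), null_config.n_permutations, null_config.seed
    )
    for result in live:
        members = by_id[result.pathway_id].members
        p_idx = np.array([table.index_of(g) for g in members if g in table])
        observed = float(batch_scores(Z, q_idx, p_idx, config)[0])
        if not np.isclose(observed, result.score, atol=1e-9):
            raise ValueError(
                f"{result.pathway_id}: stored score {result.score:.6g} does not match "
                f"the scoring config (recomputed {observed:.6g}); beta/threshold mismatch?"
            )
        null = NullDistribution(
            result.pathway_id,
            batch_scores(Z, null_idx, p_idx, config),
            config.beta,
            config.corr_threshold,
        )
        result.pvalue = empirical_pvalue(result.score, null.scores)
    adjusted = bh_adjust([r.pvalue for r in live])
    for result, bh in zip(live, adjusted):
        result.bh = float(bh)
    return results
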