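"""Synthetic toy-scale inputs for every stage of the pipeline.

Real runs take a STRING-scale PPI network, protein sequences and curated
pathway databases; these generators emulate each of them at desk scale:

* a stochastic block model (SBM) graph as a community-structured PPI
  network,
* uniform random amino-acid sequences,
* planted embeddings with a controlled within-community Pearson
  correlation (a surrogate for trained protein embeddings that lets the
  scoring and significance layers be validated independently of encoder
  quality),
* pathway collections spanning the two detection regimes: overlap-rich
  pathways sharing members with the query, and overlap-free pathways
  that are disjoint from the query but drawn from its correlation block
  (detectable only through interaction signal).

All generators are pure functions of their spec plus seed, and all
fixture identifiers share one namespace (P0001, P0002, ...) so files can
be cross-referenced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import CANONICAL_AA, EdgeList, EmbeddingTable, GeneSet, GeneSetCollection, QueryList

__all__ = [
    "SBMSpec",
    "PlantedEmbeddingSpec",
    "sbm_block_assignment",
    "generate_sbm_graph",
    "generate_sequences",
    "generate_planted_embeddings",
    "generate_pathway_collection",
    "generate_mixed_collection",
]


def _node_name(i: int) -> str:
    return f"P{i + 1:04d}"


@dataclass(frozen=True)
class SBMSpec:
    """Stochastic block model: n_nodes split near-evenly into
    n_communities, within-community edge probability p_in and
    cross-community probability p_out."""

    n_nodes: int = 120
    n_communities: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_nodes < self.n_communities:
            raise ValueError("n_nodes must be >= n_communities")

    @property
    def sizes(self) -> list[int]:
        base, extra = divmod(self.n_nodes, self.n_communities)
        return [base + (1 if c < extra else 0) for c in range(self.n_communities)]


def sbm_block_assignment(spec: SBMSpec) -> dict[str, int]:
    """Deterministic node -> community map (blocks are contiguous index
    ranges)."""
    out: dict[str, int] = {}
    i = 0
    for block, size in enumerate(spec.sizes):
        for _ in range(size):
            out[_node_name(i)] = block
            i += 1
    return out


def generate_sbm_graph(spec: SBMSpec) -> EdgeList:
    """Sample an undirected simple SBM graph as a STRING-style edge list
    (all scores 999)."""
    p = np.full((spec.n_communities, spec.n_communities), spec.p_out)
    np.fill_diagonal(p, spec.p_in)
    g = nx.stochastic_block_model(spec.sizes, p.tolist(), seed=int(spec.seed))
    edges = [(_node_name(a), _node_name(b), 999.0) for a, b in g.edges()]
    return EdgeList(edges)


def generate_sequences(n: int, min_len: int = 50, max_len: int = 200, seed: int = 0) -> str:
    """FASTA text of n uniform random amino-acid sequences (ids P0001...)."""
    if min_len < 1 or max_len < min_len:
        raise ValueError("need 1 <= min_len <= max_len")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(CANONICAL_AA))
    records = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        records.append(f">{_node_name(i)}\n{seq}\n")
    return "".join(records)


@dataclass(frozen=True)
class PlantedEmbeddingSpec:
    """Embeddings with tunable within-block correlation: each vector is
    sqrt(rho) * (shared block vector) + sqrt(1 - rho) * iid noise, all
    coordinates standard normal, so within-block pairwise Pearson
    correlation concentrates around rho."""

    dim: int = 128
    rho: float = 0.95
    blocks: tuple[tuple[str, ...], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 3:
            raise ValueError("dim must be >= 3")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not self.blocks:
            raise ValueError("blocks must be non-empty")

    @classmethod
    def from_assignment(
        cls, assignment: dict[str, int], dim: int = 128, rho: float = 0.95, seed: int = 0
    ) -> "PlantedEmbeddingSpec":
        n_blocks = max(assignment.values()) + 1
        blocks = tuple(
            tuple(p for p, b in assignment.items() if b == block) for block in range(n_blocks)
        )
        return cls(dim=dim, rho=rho, blocks=blocks, seed=seed)


def generate_planted_embeddings(spec: PlantedEmbeddingSpec) -> EmbeddingTable:
    rng = np.random.default_rng(spec.seed)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for members in spec.blocks:
        shared = rng.standard_normal(spec.dim)
        for ident in members:
            noise = rng.standard_normal(spec.dim)
            ids.append(ident)
            rows.append(np.sqrt(spec.rho) * shared + np.sqrt(1 - spec.rho) * noise)
    return EmbeddingTable(ids, np.array(rows))


def _draw(rng: np.random.Generator, pool: list[str], k: int) -> list[str]:
    if k > len(pool):
        raise ValueError(f"cannot draw {k} from a pool of {len(pool)}")
    return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]


def generate_pathway_collection(
    blocks: tuple[tuple[str, ...], ...],
    scenario: str,
    seed: int = 0,
    n_pathways: int = 5,
    query_size: int = 10,
    pathway_size: int = 12,
    share: float = 0.5,
) -> tuple[GeneSetCollection, QueryList]:
    """Build (collection, query) for one detection scenario.

    The query is always drawn from block 0 and depends only on (blocks,
    seed, query_size), so collections generated for different scenarios
    under the same seed refer to the same query and can be merged.

    * overlap_rich — each pathway contains round(share * query_size)
      query members plus cross-block fillers.
    * overlap_free_linked — pathways disjoint from the query but drawn
      from the query's block (interaction/correlation signal only).
    * unrelated — pathways disjoint from the query and cross-block.
    """
    if scenario not in ("overlap_rich", "overlap_free_linked", "unrelated"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng_q = np.random.default_rng(seed)
    block0 = list(blocks[0])
    query = QueryList(tuple(sorted(_draw(rng_q, block0, query_size))), f"query-{seed}")
    others = [p for block in blocks[1:] for p in block]
    rest0 = [p for p in block0 if p not in query.identifiers]

    rng_p = np.random.default_rng((seed * 7 + hash(scenario) % 1000) % (2**31))
    sets = []
    for i in range(n_pathways):
        if scenario == "overlap_rich":
            n_shared = int(round(share * query_size))
            members = _draw(rng_p, list(query.identifiers), n_shared)
            members += _draw(rng_p, others, pathway_size - n_shared)
        elif scenario == "overlap_free_linked":
            members = _draw(rng_p, rest0, pathway_size)
        else:
            members = _draw(rng_p, others, pathway_size)
        sets.append(GeneSet(f"{scenario.upper()}_{i + 1}", scenario, tuple(members)))
    return GeneSetCollection(scenario, tuple(sets)), query


def generate_mixed_collection(
    blocks: tuple[tuple[str, ...], ...],
    seed: int = 0,
    n_per_scenario: int = 5,
    query_size: int = 10,
    pathway_size: int = 12,
    share: float = 0.5,
) -> tuple[GeneSetCollection, QueryList]:
    """All three scenarios merged into one collection (shared query)."""
    merged: list[GeneSet] = []
    query = None
    for scenario in ("overlap_rich", "overlap_free_linked", "unrelated"):
        coll, query = generate_pathway_collection(
            blocks, scenario, seed, n_per_scenario, query_size, pathway_size, share
        )
        merged.extend(coll.sets)
    return GeneSetCollection("mixed", tuple(merged)), query
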