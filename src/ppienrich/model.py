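"""Model/Results front end tying the pipeline stages together.

Two fitted-model pairs mirror the two learnable/derived layers:

* :class:`PPILinkModel` — the link-prediction encoder fitted to a PPI
  graph; its :class:`PPILinkResults` carries the learned embeddings,
  per-epoch training history and the held-out link AUC.
* :class:`PathwayEnrichment` — a query scored against a pathway
  collection on a given embedding table; its :class:`EnrichmentResults`
  carries per-pathway scores, permutation p-values and BH-adjusted
  p-values, with a summary() table and TSV export.
"""

from __future__ import annotations

import copy

import pandas as pd

from . import io as _io
from .encoder import EncoderConfig, PPIGraph, encode_proteins, train_encoder
from .io import EdgeList, EmbeddingTable, GeneSetCollection, QueryList
from .scoring import EnrichmentResult, ScoringConfig, enrich
from .significance import NullConfig, assess

__all__ = ["PPILinkModel", "PPILinkResults", "PathwayEnrichment", "EnrichmentResults"]


class PPILinkModel:
    """Link-prediction embedding model over a PPI graph."""

    def __init__(self, graph: PPIGraph, config: EncoderConfig | None = None):
        self.graph = graph
        self.config = config or EncoderConfig()

    def fit(self) -> "PPILinkResults":
        model = train_encoder(self.graph, self.config)
        return PPILinkResults(self, model)


class PPILinkResults:
    def __init__(self, model: PPILinkModel, encoder_model):
        self.model = model
        self.encoder_model = encoder_model
        self.history = encoder_model.history
        self.val_auc = encoder_model.final_val_auc

    def embedding_table(self) -> EmbeddingTable:
        return encode_proteins(self.encoder_model, self.model.graph)

    def summary(self) -> str:
        cfg = self.model.config
        g = self.model.graph
        lines = [
            "PPI link-prediction encoder",
            "===========================",
            f"nodes: {g.n_nodes}   edges: {g.n_edges} "
            f"(train {len(self.encoder_model.train_edges)}, "
            f"test {len(self.encoder_model.test_edges)})",
            f"embedding dim: {cfg.embedding_dim}   layers: {cfg.conv_layers}   "
            f"front end: {cfg.sequence_pool}",
            f"epochs: {cfg.epochs}   lr: {cfg.learning_rate}   seed: {cfg.seed}",
            f"final train loss: {self.history['loss'][-1]:.4f}"
            if self.history["loss"]
            else "final train loss: n/a (0 epochs)",
            f"held-out link AUC: {self.val_auc:.4f}",
        ]
        return "\n".join(lines)


class PathwayEnrichment:
    """Enrichment of a query gene list against a pathway collection.

    Scores are computed on the embedding table; fit() optionally attaches
    permutation p-values and BH-adjusted p-values.
    """

    def __init__(
        self,
        query: QueryList,
        collection: GeneSetCollection,
        table: EmbeddingTable,
        edges: EdgeList | None = None,
        config: ScoringConfig | None = None,
    ):
        self.query = query
        self.collection = collection
        self.table = table
        self.edges = edges
        self.config = config or ScoringConfig()

    def fit(self, null_config: NullConfig | None = None) -> "EnrichmentResults":
        results = enrich(self.query, self.collection, self.table, self.config, self.edges)
        if null_config is not None:
            results = assess(
                results, self.query, self.collection, self.table, self.config, null_config
            )
        return EnrichmentResults(self, results, null_config)


class EnrichmentResults:
    def __init__(
        self,
        model: PathwayEnrichment,
        results: list[EnrichmentResult],
        null_config: NullConfig | None,
    ):
        self.model = model
        self.results = results
        self.null_config = null_config

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {c: getattr(r, c) for c in _io.RESULT_COLUMNS + ["skipped"]}
                for r in self.results
            ]
        )
        return df.sort_values(
            by=["bh", "pvalue", "score", "pathway_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        _io.write_results(self.results, path)

    def n_significant(self, alpha: float = 0.05) -> int:
        return int(sum(1 for r in self.results if not r.skipped and r.bh < alpha))

    def summary(self, top: int = 10) -> str:
        cfg = self.model.config
        df = self.to_frame().head(top)
        header = [
            "Pathway enrichment",
            "==================",
            f"query: {self.model.query.label} ({len(self.model.query)} genes)   "
            f"collection: {self.model.collection.name} ({len(self.model.collection)} pathways)",
            f"beta: {cfg.beta}   corr threshold: {cfg.corr_threshold}",
        ]
        if self.null_config is not None:
            header.append(
                f"permutations: {self.null_config.n_permutations}   "
                f"significant (BH<0.05): {self.n_significant()}"
            )
        with pd.option_context("display.width", 120):
            body = df.to_string(
                index=False,
                float_format=lambda x: f"{x:.4g}",
            )
        return "\n".join(header + ["", body])

    def rescored(self, beta: float) -> "EnrichmentResults":
        """Re-fit under a different beta (nulls are recomputed: they depend
        on beta)."""
        model = copy.copy(self.model)
        model.config = ScoringConfig(
            beta=beta,
            corr_threshold=self.model.config.corr_threshold,
            missing_as_zero=self.model.config.missing_as_zero,
        )
        return model.fit(self.null_config)


def beta_scan(
    query: QueryList,
    collection: GeneSetCollection,
    table: EmbeddingTable,
    betas,
    edges: EdgeList | None = None,
    corr_threshold: float = 0.9,
    null_config: NullConfig | None = None,
) -> pd.DataFrame:
    """Long-format per-beta enrichment table (pathway, beta, score, p, bh).

    Null distributions are recomputed for every beta, since the null
    scores themselves depend on it.
    """
    betas = list(betas)
    if not betas or any(b < 1 for b in betas):
        raise ValueError("beta list must be non-empty with all values >= 1")
    frames = []
    for beta in betas:
        fit = PathwayEnrichment(
            query, collection, table, edges, ScoringConfig(beta=beta, corr_threshold=corr_threshold)
        ).fit(null_config)
        df = fit.to_frame()
        df.insert(1, "beta", float(beta))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["beta", "bh", "pvalue", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )
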