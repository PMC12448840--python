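"""Graph encoder: learn per-protein embeddings hP by link prediction.

The architecture follows the GIN lineage of sum-aggregation message
passing.  A sequence front end turns each protein's amino-acid features
into a fixed-size node vector — either the 20-dim composition shortcut or
a trainable 1-D convolution with global average pooling over the
position-resolved feature matrix — and a stack of graph convolution
layers

    H_(l) = relu( (A + (1+eps) I) H_(l-1) W_l + b_l )

produces the embedding hP (no nonlinearity after the last layer).  An
edge (u, v) is scored by the logistic squashing of the embedding inner
product; training minimises binary cross-entropy over observed edges and
uniformly resampled non-edges.

Everything is plain numpy with hand-derived gradients and Adam updates;
training is deterministic given the config seed.  Message passing during
training uses only the train-split adjacency so the held-out AUC is an
honest link-prediction measure; exported embeddings use the full graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .io import EdgeList, EmbeddingTable
from .sequence_features import ProteinFeatureMatrix
from .utils import SEED_INIT, SEED_NEGATIVES, SEED_SPLIT, derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "EncoderConfig",
    "PPIGraph",
    "EncoderModel",
    "build_graph",
    "split_edges",
    "train_encoder",
    "encode_proteins",
    "tune_embedding_dim",
]


@dataclass(frozen=True)
class EncoderConfig:
    embedding_dim: int = 64
    conv_layers: int = 2
    hidden_dim: int = 64
    sequence_pool: str = "conv1d"  # or the "mean-composition" shortcut
    learning_rate: float = 0.03
    epochs: int = 200
    negative_ratio: float = 1.0
    train_fraction: float = 0.8
    seed: int = 0
    conv_filters: int = 32
    conv_kernel: int = 9
    gin_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.embedding_dim < 3:
            raise ValueError("embedding_dim must be >= 3")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.conv_layers < 1:
            raise ValueError("need at least one graph convolution layer")
        if self.sequence_pool not in ("mean-composition", "conv1d"):
            raise ValueError(f"unknown sequence_pool {self.sequence_pool!r}")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be positive")


@dataclass(frozen=True)
class PPIGraph:
    """Undirected simple PPI graph with per-node sequence features.

    edge_index holds (i, j) node-index pairs with i < j; the adjacency is
    symmetric and irreflexive by construction.
    """

    node_ids: tuple[str, ...]
    edge_index: np.ndarray  # (E, 2) int
    features: Mapping[str, np.ndarray | ProteinFeatureMatrix] = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    def adjacency(self, edge_index: np.ndarray | None = None) -> np.ndarray:
        idx = self.edge_index if edge_index is None else edge_index
        A = np.zeros((self.n_nodes, self.n_nodes))
        if len(idx):
            A[idx[:, 0], idx[:, 1]] = 1.0
            A[idx[:, 1], idx[:, 0]] = 1.0
        return A


def build_graph(
    edges: EdgeList, features: Mapping[str, np.ndarray | ProteinFeatureMatrix]
) -> PPIGraph:
    """Assemble the graph G from an edge list and per-protein features.

    Edges whose endpoints lack a feature entry are dropped with a warning;
    node order is the sorted retained identifiers.
    """
    missing = {p for a, b, _ in edges.edges for p in (a, b) if p not in features}
    if missing:
        logger.warning(
            "dropping edges touching %d proteins without features: %s",
            len(missing),
            sorted(missing)[:10],
        )
    kept = [(a, b) for a, b, _ in edges.edges if a not in missing and b not in missing]
    if not kept:
        raise ValueError("no usable edges after dropping feature-less endpoints")
    node_ids = tuple(sorted({p for ab in kept for p in ab}))
    index = {p: i for i, p in enumerate(node_ids)}
    pairs = sorted({(min(index[a], index[b]), max(index[a], index[b])) for a, b in kept})
    return PPIGraph(node_ids, np.array(pairs, dtype=int), dict(features))


def split_edges(
    graph: PPIGraph, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test edge split; |train| = round(fraction * |E|)."""
    if graph.n_edges < 5:
        raise ValueError("need at least 5 edges to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(graph.n_edges)
    n_train = int(round(train_fraction * graph.n_edges))
    train = graph.edge_index[np.sort(order[:n_train])]
    test = graph.edge_index[np.sort(order[n_train:])]
    degree = np.zeros(graph.n_nodes, dtype=int)
    for i, j in train:
        degree[i] += 1
        degree[j] += 1
    isolated = int((degree == 0).sum())
    if isolated:
        logger.info("train split leaves %d node(s) isolated", isolated)
    return train, test


# ---------------------------------------------------------------------------
# internals: feature assembly, forward/backward, Adam


def _propagation_matrix(
    graph: PPIGraph, edge_index: np.ndarray, config: EncoderConfig
) -> np.ndarray:
    """Sum-aggregation operator A + (1+eps)I, rescaled by the mean degree.

    The global rescaling keeps per-node degree contrasts (the GIN
    property) while preventing the activations from growing by a factor
    of the mean degree at every layer, which saturates the logistic
    decoder and stalls training.
    """
    A = graph.adjacency(edge_index)
    mean_degree = max(A.sum(axis=1).mean(), 1.0)
    return (A + (1.0 + config.gin_eps) * np.eye(graph.n_nodes)) / mean_degree


def _assemble_inputs(graph: PPIGraph, config: EncoderConfig) -> dict:
    """Stack node features in node order for the configured front end."""
    feats = [graph.features[p] for p in graph.node_ids]
    if config.sequence_pool == "mean-composition":
        if not all(isinstance(f, np.ndarray) and f.ndim == 1 for f in feats):
            raise ValueError("mean-composition front end needs 1-D feature vectors")
        X0 = np.stack(feats).astype(float)
        # column-standardize: composition vectors are nearly constant across
        # proteins (all compositions hover around the alphabet frequencies),
        # and without centering the constant component dominates every
        # embedding, drowning the per-protein sequence identity the message
        # passing needs
        std = X0.std(axis=0)
        std[std == 0] = 1.0
        X0 = (X0 - X0.mean(axis=0)) / std
        return {"kind": "static", "X0": X0, "in_dim": X0.shape[1]}
    if not all(isinstance(f, ProteinFeatureMatrix) for f in feats):
        raise ValueError("conv1d front end needs ProteinFeatureMatrix features")
    mats = np.stack([f.matrix for f in feats])  # (n, L, C)
    masks = np.stack([f.mask for f in feats])
    k = config.conv_kernel
    # drop trailing positions padded in every protein; pure speedup
    longest = max(int(masks.sum(axis=1).max()), k)
    mats = mats[:, :longest, :]
    masks = masks[:, :longest]
    n, L, C = mats.shape
    if L < k:
        raise ValueError(f"max_length {L} shorter than conv kernel {k}")
    T = L - k + 1
    # im2col: window t of protein i flattened to k*C features
    windows = np.stack([mats[:, t : t + k, :].reshape(n, k * C) for t in range(T)], axis=1)
    lengths = masks.sum(axis=1).astype(int)
    n_valid = np.clip(lengths - k + 1, 0, T)
    valid = np.arange(T)[None, :] < n_valid[:, None]  # (n, T)
    return {
        "kind": "conv",
        "windows": windows,
        "valid": valid,
        "n_valid": n_valid,
        "in_dim": config.conv_filters,
        "kC": k * C,
    }


def _init_params(config: EncoderConfig, inputs: dict, rng: np.random.Generator) -> dict:
    def glorot(shape):
        scale = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-scale, scale, size=shape)

    params: dict[str, np.ndarray] = {}
    if inputs["kind"] == "conv":
        params["Wc"] = glorot((inputs["kC"], config.conv_filters))
        params["bc"] = np.zeros(config.conv_filters)
    dims = [inputs["in_dim"]] + [config.hidden_dim] * (config.conv_layers - 1)
    dims += [config.embedding_dim]
    for l in range(config.conv_layers):
        params[f"W{l}"] = glorot((dims[l], dims[l + 1]))
        params[f"b{l}"] = np.zeros(dims[l + 1])
    return params


def _conv_forward(params: dict, inputs: dict) -> tuple[np.ndarray, dict]:
    P = inputs["windows"] @ params["Wc"] + params["bc"]  # (n, T, F)
    R = np.maximum(P, 0.0)
    denom = np.maximum(inputs["n_valid"], 1)[:, None]
    pooled = (R * inputs["valid"][:, :, None]).sum(axis=1) / denom
    # batch-center the pooled features: relu-pooled conv outputs of protein
    # sequences are nearly constant across proteins, and the constant
    # component carries no identity (same failure mode as raw compositions)
    X0 = pooled - pooled.mean(axis=0)
    return X0, {"P": P}


def _conv_backward(params: dict, inputs: dict, cache: dict, dX0: np.ndarray) -> dict:
    dpooled = dX0 - dX0.mean(axis=0)
    denom = np.maximum(inputs["n_valid"], 1)[:, None, None]
    dR = (dpooled[:, None, :] * inputs["valid"][:, :, None]) / denom
    dP = dR * (cache["P"] > 0)
    return {
        "Wc": np.einsum("ntk,ntf->kf", inputs["windows"], dP),
        "bc": dP.sum(axis=(0, 1)),
    }


def _forward(params: dict, S: np.ndarray, inputs: dict, config: EncoderConfig):
    cache: dict = {}
    if inputs["kind"] == "conv":
        X0, cache["conv"] = _conv_forward(params, inputs)
    else:
        X0 = inputs["X0"]
    cache["acts"] = [X0]  # layer inputs
    cache["pre"] = []
    cache["SH"] = []
    H = X0
    for l in range(config.conv_layers):
        SH = S @ H
        M = SH @ params[f"W{l}"] + params[f"b{l}"]
        cache["SH"].append(SH)
        cache["pre"].append(M)
        H = np.maximum(M, 0.0) if l < config.conv_layers - 1 else M
        cache["acts"].append(H)
    return H, cache


def _backward(
    params: dict, S: np.ndarray, inputs: dict, config: EncoderConfig, cache: dict, dZ: np.ndarray
) -> dict:
    grads: dict[str, np.ndarray] = {}
    dH = dZ
    for l in range(config.conv_layers - 1, -1, -1):
        dM = dH if l == config.conv_layers - 1 else dH * (cache["pre"][l] > 0)
        grads[f"W{l}"] = cache["SH"][l].T @ dM
        grads[f"b{l}"] = dM.sum(axis=0)
        dH = S @ (dM @ params[f"W{l}"].T)  # S symmetric
    if inputs["kind"] == "conv":
        grads.update(_conv_backward(params, inputs, cache["conv"], dH))
    return grads


def _pair_loss_grad(
    Z: np.ndarray, u: np.ndarray, v: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean BCE over node pairs and its gradient w.r.t. the embeddings."""
    s = np.einsum("ij,ij->i", Z[u], Z[v])
    # log(1 + e^s) - y*s, computed stably
    loss = float(np.mean(np.logaddexp(0.0, s) - y * s))
    p = 1.0 / (1.0 + np.exp(-s))
    g = (p - y) / len(s)
    dZ = np.zeros_like(Z)
    np.add.at(dZ, u, g[:, None] * Z[v])
    np.add.at(dZ, v, g[:, None] * Z[u])
    return loss, dZ


def _loss_and_grads(
    params: dict,
    S: np.ndarray,
    inputs: dict,
    config: EncoderConfig,
    u: np.ndarray,
    v: np.ndarray,
    y: np.ndarray,
) -> tuple[float, dict]:
    Z, cache = _forward(params, S, inputs, config)
    loss, dZ = _pair_loss_grad(Z, u, v, y)
    return loss, _backward(params, S, inputs, config, cache, dZ)


def _sample_non_edges(
    n_nodes: int, forbidden: set[tuple[int, int]], count: int, rng: np.random.Generator
) -> np.ndarray:
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    while len(out) < count:
        cand = rng.integers(0, n_nodes, size=(max(count * 2, 16), 2))
        for a, b in cand:
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key in forbidden or key in seen:
                continue
            seen.add(key)
            out.append(key)
            if len(out) == count:
                break
    return np.array(out, dtype=int)


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p in params.items()}
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class EncoderModel:
    """Trained encoder: learned parameters w, config and training history."""

    params: dict
    config: EncoderConfig
    node_ids: tuple[str, ...]
    train_edges: np.ndarray
    test_edges: np.ndarray
    history: dict = field(default_factory=dict)
    final_val_auc: float = float("nan")

    def edge_scores(self, Z: np.ndarray, pairs: np.ndarray) -> np.ndarray:
        s = np.einsum("ij,ij->i", Z[pairs[:, 0]], Z[pairs[:, 1]])
        return 1.0 / (1.0 + np.exp(-s))


def _validation_auc(
    Z: np.ndarray, test_edges: np.ndarray, test_negatives: np.ndarray
) -> float:
    pos = np.einsum("ij,ij->i", Z[test_edges[:, 0]], Z[test_edges[:, 1]])
    neg = np.einsum("ij,ij->i", Z[test_negatives[:, 0]], Z[test_negatives[:, 1]])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return float(roc_auc_score(labels, np.concatenate([pos, neg])))


def train_encoder(
    graph: PPIGraph,
    config: EncoderConfig,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> EncoderModel:
    """Fit the link-prediction encoder; deterministic under config.seed."""
    if split is None:
        split = split_edges(graph, config.train_fraction, derive_seed(config.seed, SEED_SPLIT))
    train, test = split
    inputs = _assemble_inputs(graph, config)
    rng_init = np.random.default_rng(derive_seed(config.seed, SEED_INIT))
    rng_neg = np.random.default_rng(derive_seed(config.seed, SEED_NEGATIVES))
    params = _init_params(config, inputs, rng_init)

    S = _propagation_matrix(graph, train, config)
    # training negatives may coincide with held-out test edges: excluding
    # them would leak the test set (pairs never seen as negatives become
    # identifiable), inflating the held-out AUC even on structureless graphs
    train_edge_set = {(int(i), int(j)) for i, j in train}
    all_edges = {(int(i), int(j)) for i, j in graph.edge_index}
    n_neg_train = int(round(config.negative_ratio * len(train)))
    test_negatives = _sample_non_edges(graph.n_nodes, all_edges, max(len(test), 1), rng_neg)

    optimizer = _Adam(params, config.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "val_auc": []}
    for epoch in range(config.epochs):
        neg = _sample_non_edges(graph.n_nodes, train_edge_set, n_neg_train, rng_neg)
        u = np.concatenate([train[:, 0], neg[:, 0]])
        v = np.concatenate([train[:, 1], neg[:, 1]])
        y = np.concatenate([np.ones(len(train)), np.zeros(len(neg))])
        loss, grads = _loss_and_grads(params, S, inputs, config, u, v, y)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}; lower the learning rate")
        optimizer.step(params, grads)
        Z, _ = _forward(params, S, inputs, config)
        auc = _validation_auc(Z, test, test_negatives) if len(test) else float("nan")
        history["loss"].append(loss)
        history["val_auc"].append(auc)
        if epoch % 50 == 0 or epoch == config.epochs - 1:
            logger.info("epoch %d loss %.4f val AUC %.3f", epoch, loss, auc)

    Z, _ = _forward(params, S, inputs, config)
    final_auc = _validation_auc(Z, test, test_negatives) if len(test) else float("nan")
    return EncoderModel(params, config, graph.node_ids, train, test, history, final_auc)


def encode_proteins(model: EncoderModel, graph: PPIGraph) -> EmbeddingTable:
    """Encode every node of *graph* with the trained parameters.

    Inference message passing uses the full edge set; output is one
    embedding_dim vector per node.
    """
    inputs = _assemble_inputs(graph, model.config)
    if inputs["in_dim"] != model.params["W0"].shape[0]:
        raise ValueError(
            f"feature dimensionality {inputs['in_dim']} does not match the "
            f"trained model ({model.params['W0'].shape[0]})"
        )
    S = _propagation_matrix(graph, graph.edge_index, model.config)
    Z, _ = _forward(model.params, S, inputs, model.config)
    return EmbeddingTable(graph.node_ids, Z)


def tune_embedding_dim(
    graph: PPIGraph, candidate_dims: Sequence[int], config: EncoderConfig
) -> EncoderConfig:
    """Grid search over embedding dims, selecting by held-out link AUC.

    Ties are broken toward the smaller dimension; the split is shared
    across candidates (same seed).
    """
    if not candidate_dims:
        raise ValueError("candidate_dims must be non-empty")
    best_dim, best_auc = None, -np.inf
    for dim in sorted(candidate_dims):
        model = train_encoder(graph, replace(config, embedding_dim=dim))
        logger.info("dim %d -> val AUC %.3f", dim, model.final_val_auc)
        if model.final_val_auc > best_auc:
            best_dim, best_auc = dim, model.final_val_auc
    return replace(config, embedding_dim=best_dim)
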