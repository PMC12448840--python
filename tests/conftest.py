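"""Shared fixtures: a small planted-embedding world and an SBM graph world.

Everything is generated programmatically; session scope keeps the heavier
objects (trained encoders, embedding tables) shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppienrich.encoder import EncoderConfig, build_graph, train_encoder
from ppienrich.io import read_fasta
from ppienrich.sequence_features import ResidueFeatureConfig, featurize_sequence
from ppienrich.synthetic import (
    PlantedEmbeddingSpec,
    SBMSpec,
    generate_mixed_collection,
    generate_planted_embeddings,
    generate_sbm_graph,
    generate_sequences,
    sbm_block_assignment,
)


@pytest.fixture(scope="session")
def sbm_spec():
    return SBMSpec(n_nodes=120, n_communities=4, p_in=0.3, p_out=0.01, seed=7)


@pytest.fixture(scope="session")
def sbm_edges(sbm_spec):
    return generate_sbm_graph(sbm_spec)


@pytest.fixture(scope="session")
def block_assignment(sbm_spec):
    return sbm_block_assignment(sbm_spec)


@pytest.fixture(scope="session")
def planted_spec(block_assignment):
    return PlantedEmbeddingSpec.from_assignment(block_assignment, dim=128, rho=0.95, seed=7)


@pytest.fixture(scope="session")
def planted_table(planted_spec):
    return generate_planted_embeddings(planted_spec)


@pytest.fixture(scope="session")
def mixed_world(planted_spec):
    """(collection, query) with overlap-rich, overlap-free-linked and
    unrelated pathways over the planted blocks."""
    return generate_mixed_collection(planted_spec.blocks, seed=7)


@pytest.fixture(scope="session")
def sbm_graph(sbm_spec, sbm_edges, tmp_path_factory):
    fasta = tmp_path_factory.mktemp("fa") / "p.fasta"
    fasta.write_text(generate_sequences(sbm_spec.n_nodes, seed=7))
    seqs = read_fasta(fasta)
    cfg = ResidueFeatureConfig()
    features = {p: featurize_sequence(p, s, cfg) for p, s in seqs.items()}
    return build_graph(sbm_edges, features)


@pytest.fixture(scope="session")
def trained_model(sbm_graph):
    return train_encoder(sbm_graph, EncoderConfig(seed=7, epochs=60))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
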