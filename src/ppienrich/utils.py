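"""Small shared helpers: seed derivation and row standardization."""

from __future__ import annotations

import numpy as np

# Fixed offsets so one user-facing seed fans out deterministically to every
# random sub-stream of a run (documented in the methods note).
SEED_SPLIT = 1
SEED_INIT = 2
SEED_NEGATIVES = 3
SEED_NULL = 4
SEED_FIXTURES = 5


def derive_seed(seed: int, offset: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return (int(seed) + 0x9E3779B1 * int(offset)) % (2**31)


def standardize_rows(matrix: np.ndarray) -> np.ndarray:
    """Center each row and scale it to unit Euclidean norm.

    Dot products of standardized rows are Pearson correlations of the raw
    rows.  Zero-variance rows are mapped to the zero vector, realising the
    r = 0 convention for degenerate embeddings.
    """
    matrix = np.asarray(matrix, dtype=float)
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    out = np.zeros_like(centered)
    nonzero = norms[:, 0] > 0
    out[nonzero] = centered[nonzero] / norms[nonzero]
    return out
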