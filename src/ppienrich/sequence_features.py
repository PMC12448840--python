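"""Per-protein raw feature construction from amino-acid sequences.

Two encodings are provided as seeds for the graph encoder:

* :func:`featurize_sequence` — a position-resolved matrix of shape
  (max_length, 27): a 20-channel residue one-hot plus 7 physicochemical
  group channels (aliphatic, aromatic, positively charged, negatively
  charged, polar uncharged, cysteine, proline), padded/truncated to a
  fixed length with an explicit mask.  This feeds the 1-D convolutional
  sequence front end.
* :func:`composition_vector` — the 20-dim residue frequency vector, the
  cheap front end when no convolution is trained.

The 7 groups partition the 20 canonical residues; the unknown residue X
contributes nothing to either channel set (its row is all-zero but still
marked as a real position in the mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CANONICAL_AA

#: The classic 7-class physicochemical grouping (a partition of the 20
#: canonical residues; cysteine and proline kept apart for their special
#: covalent / conformational roles).
PROPERTY_GROUPS: dict[str, str] = {
    "aliphatic": "AGILMV",
    "aromatic": "FWY",
    "positive": "HKR",
    "negative": "DE",
    "polar_uncharged": "NQST",
    "cysteine": "C",
    "proline": "P",
}

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
_GROUP_INDEX = {
    aa: gi for gi, (_, members) in enumerate(PROPERTY_GROUPS.items()) for aa in members
}

N_RESIDUE_CHANNELS = 20
N_GROUP_CHANNELS = len(PROPERTY_GROUPS)
N_CHANNELS = N_RESIDUE_CHANNELS + N_GROUP_CHANNELS


@dataclass(frozen=True)
class ResidueFeatureConfig:
    """Configuration for the position-resolved sequence encoding.

    max_length is the truncate/pad target: longer sequences keep their
    N-terminal prefix, shorter ones are zero-padded.
    """

    max_length: int = 512
    property_groups: tuple[str, ...] = tuple(PROPERTY_GROUPS)
    include_onehot: bool = True

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        covered = "".join(PROPERTY_GROUPS[g] for g in self.property_groups)
        if sorted(covered) != sorted(CANONICAL_AA):
            raise ValueError("property groups must partition the 20 canonical residues")


@dataclass(frozen=True)
class ProteinFeatureMatrix:
    identifier: str
    matrix: np.ndarray  # (max_length, 27)
    mask: np.ndarray = field(repr=False)  # (max_length,) 1 = real position

    @property
    def length(self) -> int:
        return int(self.mask.sum())


def featurize_sequence(
    identifier: str, seq: str, config: ResidueFeatureConfig | None = None
) -> ProteinFeatureMatrix:
    """Encode a sequence as a fixed-shape (max_length, 27) feature matrix.

    Each canonical residue sets exactly one residue channel and one group
    channel; X rows stay all-zero.  The output shape depends only on the
    config, never on the sequence.
    """
    config = config or ResidueFeatureConfig()
    if not seq:
        raise ValueError("empty sequence")
    unknown = set(seq) - set(CANONICAL_AA) - {"X"}
    if unknown:
        raise ValueError(f"unknown residues {sorted(unknown)}; map to X upstream")
    L = min(len(seq), config.max_length)
    matrix = np.zeros((config.max_length, N_CHANNELS))
    mask = np.zeros(config.max_length)
    mask[:L] = 1.0
    for pos in range(L):
        aa = seq[pos]
        if aa == "X":
            continue
        if config.include_onehot:
            matrix[pos, _AA_INDEX[aa]] = 1.0
        matrix[pos, N_RESIDUE_CHANNELS + _GROUP_INDEX[aa]] = 1.0
    return ProteinFeatureMatrix(identifier, matrix, mask)


def composition_vector(seq: str) -> np.ndarray:
    """20-dim residue frequency vector; X is excluded from both numerator
    and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    unknown = set(seq) - set(CANONICAL_AA) - {"X"}
    if unknown:
        raise ValueError(f"unknown residues {sorted(unknown)}; map to X upstream")
    counts = np.zeros(N_RESIDUE_CHANNELS)
    for aa in seq:
        if aa != "X":
            counts[_AA_INDEX[aa]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no canonical residues")
    return counts / total
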