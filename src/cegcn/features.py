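"""Common-neighbor structural node features and their one-hot encoding.

Each node's structural score at age t is the row sum of the squared adjacency
matrix, f_t(i) = (A_t^2 · 1)_i = degree(i) + sum_j |N(i) ∩ N(j)| — the node's
degree plus its total common-neighbor count with every other node.  Scores
are one-hot encoded against a vocabulary of score values collected from the
*training* snapshots only (one slot per distinct value, ascending, plus one
out-of-vocabulary slot), so feature width is fixed over the whole age axis
and no information from held-out ages leaks into the encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import GraphSnapshot


def _check_binary_symmetric(adj: np.ndarray) -> None:
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if not np.isin(adj, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    if np.any(np.diag(adj)):
        raise ValueError("adjacency must have zero diagonal")


def squared_adjacency(snapshot: GraphSnapshot | np.ndarray) -> np.ndarray:
    """Exact integer A·A: diagonal = degrees, off-diagonal = common neighbors."""
    adj = snapshot.adjacency if isinstance(snapshot, GraphSnapshot) else snapshot
    _check_binary_symmetric(adj)
    return (adj.astype(np.int64) @ adj.astype(np.int64))


def structural_score(squared: np.ndarray) -> np.ndarray:
    """Row sums of A^2 (multiplication by the all-ones column vector)."""
    squared = np.asarray(squared)
    if squared.ndim != 2 or squared.shape[0] != squared.shape[1]:
        raise ValueError("squared adjacency must be square")
    return squared.sum(axis=1)


def snapshot_scores(snapshot: GraphSnapshot) -> np.ndarray:
    """Convenience: structural scores straight from a snapshot."""
    return structural_score(squared_adjacency(snapshot))


@dataclass(frozen=True)
class FeatureVocabulary:
    """Injective map from observed score values to one-hot slots.

    Slots 0..d-2 hold the distinct training score values in ascending order;
    slot d-1 is reserved for out-of-vocabulary values seen at inference.
    """

    value_to_slot: dict[int, int]

    @property
    def d(self) -> int:
        return len(self.value_to_slot) + 1

    @property
    def oov_slot(self) -> int:
        return self.d - 1

    def slot(self, value: int) -> int:
        return self.value_to_slot.get(int(value), self.oov_slot)

    def decode(self, slot: int) -> int | None:
        """Inverse lookup; None for the OOV slot."""
        for value, s in self.value_to_slot.items():
            if s == slot:
                return value
        return None

    def to_dict(self) -> dict:
        return {"values": sorted(self.value_to_slot), "d": self.d}

    @classmethod
    def from_values(cls, values) -> "FeatureVocabulary":
        distinct = sorted({int(v) for v in values})
        return cls({v: i for i, v in enumerate(distinct)})


def build_vocabulary(score_vectors) -> FeatureVocabulary:
    """Collect distinct score values over the given (training) snapshots."""
    score_vectors = list(score_vectors)
    if not score_vectors:
        raise ValueError("need at least one snapshot to build a vocabulary")
    return FeatureVocabulary.from_values(np.concatenate([np.ravel(s) for s in score_vectors]))


def one_hot_encode(scores: np.ndarray, vocab: FeatureVocabulary) -> np.ndarray:
    """n×d binary matrix with exactly one 1 per row (unseen values -> OOV slot)."""
    scores = np.ravel(scores)
    out = np.zeros((scores.size, vocab.d))
    for i, s in enumerate(scores):
        out[i, vocab.slot(s)] = 1.0
    return out
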