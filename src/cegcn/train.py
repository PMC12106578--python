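"""Temporal splitting, prediction targets, and ranking evaluation (MAP/MRR).

The prediction task at age t is: given embeddings computed from snapshots up
to and including t, score node pairs for the presence (all_edges) or the
appearance (new_edges) of an edge at t+1.  Evaluation forms one ranking
query per (age, node with at least one positive partner); MAP is the mean
per-query discrete average precision, MRR the mean reciprocal rank of the
first relevant partner (0 when no relevant partner is retrieved).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SnapshotSequence

TARGET_MODES = ("all_edges", "new_edges")


@dataclass(frozen=True)
class SplitSpec:
    """Contiguous temporal blocks of snapshot ages (strictly ordered)."""

    train_ages: tuple[int, ...]
    val_ages: tuple[int, ...]
    test_ages: tuple[int, ...]
    target_mode: str = "new_edges"

    def __post_init__(self):
        if self.target_mode not in TARGET_MODES:
            raise ValueError(f"target_mode must be one of {TARGET_MODES}")
        if not (self.train_ages and self.val_ages and self.test_ages):
            raise ValueError("every split block must be non-empty")
        if not (max(self.train_ages) < min(self.val_ages) < min(self.test_ages)):
            raise ValueError("split blocks must be strictly temporal")

    def prediction_ages(self, block: str) -> list[int]:
        """Ages t whose target snapshot t+1 falls inside the given block.

        For train, both t and t+1 must be train ages (no gradient may see a
        validation snapshot); for val/test, t is the age just before each
        block member, so history naturally extends across block boundaries.
        """
        if block == "train":
            ages = set(self.train_ages)
            return sorted(t for t in ages if t + 1 in ages)
        target = set(self.val_ages if block == "val" else self.test_ages)
        all_ages = set(self.train_ages) | set(self.val_ages) | set(self.test_ages)
        return sorted(t for t in all_ages if t + 1 in target)


def temporal_split(ages, fractions=(0.70, 0.15, 0.15),
                   target_mode: str = "new_edges") -> SplitSpec:
    """Split an ordered age list into contiguous train/val/test blocks.

    Block sizes are the rounded fractions, adjusted so that every block has
    at least one age (deficits are taken from the train block).
    """
    ages = list(ages)
    n = len(ages)
    if n < 3:
        raise ValueError("need at least 3 ages for a three-way temporal split")
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0) or min(fractions) <= 0:
        raise ValueError("fractions must be positive and sum to 1")
    n_train = max(1, round(f_train * n))
    n_val = max(1, round(f_val * n))
    n_test = n - n_train - n_val
    while n_test < 1:  # steal from the largest leading block
        if n_train > 1:
            n_train -= 1
        else:
            n_val -= 1
        n_test = n - n_train - n_val
    return SplitSpec(tuple(ages[:n_train]),
                     tuple(ages[n_train:n_train + n_val]),
                     tuple(ages[n_train + n_val:]),
                     target_mode=target_mode)


def make_targets(sequence: SnapshotSequence, age: int,
                 mode: str = "new_edges") -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Positive and negative unordered pairs for predicting age+1 from age.

    all_edges: positives are the edges of G_{age+1}.  new_edges: positives
    are edges of G_{age+1} absent from G_age.  Negatives are all remaining
    non-self unordered pairs, so positives ∪ negatives is a partition of the
    C(n, 2) pair universe.
    """
    if mode not in TARGET_MODES:
        raise ValueError(f"mode must be one of {TARGET_MODES}")
    nxt = sequence.snapshot_at(age + 1).edge_set()
    cur = sequence.snapshot_at(age).edge_set()
    positives = sorted(nxt - cur) if mode == "new_edges" else sorted(nxt)
    pos_set = set(positives)
    n = sequence.n_nodes
    negatives = [p for p in itertools.combinations(range(n), 2) if p not in pos_set]
    return positives, negatives


# -- ranking metrics ------------------------------------------------------

@dataclass
class EvalQuery:
    """One ranking query: candidates sorted by descending score."""

    age: int
    query_node: int
    ranking: list[tuple[int, float]]  # (partner, score), sorted
    relevant: set[int]

    def relevance_flags(self) -> list[int]:
        return [1 if partner in self.relevant else 0 for partner, _ in self.ranking]


def rank_candidates(candidates: dict[int, float]) -> list[tuple[int, float]]:
    """Descending score, ties broken by ascending partner id."""
    return sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))


def average_precision(query: EvalQuery) -> float:
    """Discrete AP: mean over relevant ranks of precision-at-that-rank."""
    flags = query.relevance_flags()
    n_relevant = len(query.relevant)
    if n_relevant == 0:
        raise ValueError("average precision is undefined for an empty relevant set")
    hits = 0
    total = 0.0
    for rank, flag in enumerate(flags, start=1):
        if flag:
            hits += 1
            total += hits / rank
    return total / n_relevant


def reciprocal_rank(query: EvalQuery) -> float:
    for rank, flag in enumerate(query.relevance_flags(), start=1):
        if flag:
            return 1.0 / rank
    return 0.0


def mean_average_precision(queries) -> float:
    queries = list(queries)
    if not queries:
        raise ValueError("MAP is undefined with zero queries")
    return float(np.mean([average_precision(q) for q in queries]))


def mean_reciprocal_rank(queries) -> float:
    queries = list(queries)
    if not queries:
        raise ValueError("MRR is undefined with zero queries")
    return float(np.mean([reciprocal_rank(q) for q in queries]))


@dataclass
class MetricsReport:
    """Aggregate ranking metrics over all (age, query node) queries."""

    map: float
    mrr: float
    ap_per_query: list[float]
    rr_per_query: list[float]
    n_queries: int
    target_mode: str
    ages: list[int]

    def to_dict(self) -> dict:
        return {"MAP": self.map, "MRR": self.mrr, "n_queries": self.n_queries,
                "target_mode": self.target_mode, "ages": list(self.ages)}


def build_queries(sequence: SnapshotSequence, ages, mode: str,
                  score_fn) -> list[EvalQuery]:
    """Exhaustive ranking queries for each prediction age.

    ``score_fn(age, pairs)`` returns one logit per unordered pair.  For
    new_edges mode, candidates are the partners not already linked at the
    query age; for all_edges, every other node is a candidate.  Queries with
    no positive partner are skipped.
    """
    queries: list[EvalQuery] = []
    n = sequence.n_nodes
    for age in ages:
        positives, _ = make_targets(sequence, age, mode)
        if not positives:
            continue
        relevant_of: dict[int, set[int]] = {}
        for i, j in positives:
            relevant_of.setdefault(i, set()).add(j)
            relevant_of.setdefault(j, set()).add(i)
        current_edges = sequence.snapshot_at(age).edge_set()
        pairs: list[tuple[int, int]] = []
        owners: list[tuple[int, int]] = []  # (query node, partner)
        for q, relevant in sorted(relevant_of.items()):
            for partner in range(n):
                if partner == q:
                    continue
                if mode == "new_edges" and (min(q, partner), max(q, partner)) in current_edges:
                    continue
                pairs.append((q, partner))
                owners.append((q, partner))
        scores = np.asarray(score_fn(age, pairs), dtype=float)
        per_query: dict[int, dict[int, float]] = {}
        for (q, partner), s in zip(owners, scores):
            per_query.setdefault(q, {})[partner] = float(s)
        for q, relevant in sorted(relevant_of.items()):
            queries.append(EvalQuery(age=age, query_node=q,
                                     ranking=rank_candidates(per_query[q]),
                                     relevant=set(relevant)))
    return queries


def evaluate_queries(queries, target_mode: str) -> MetricsReport:
    queries = list(queries)
    if not queries:
        raise ValueError("no queries with positive targets: metrics undefined")
    aps = [average_precision(q) for q in queries]
    rrs = [reciprocal_rank(q) for q in queries]
    return MetricsReport(map=float(np.mean(aps)), mrr=float(np.mean(rrs)),
                         ap_per_query=aps, rr_per_query=rrs,
                         n_queries=len(queries), target_mode=target_mode,
                         ages=sorted({q.age for q in queries}))


def random_ranking_mrr(queries, n_samples: int = 2000,
                       rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Monte-Carlo mean and variance of MRR under uniformly random rankings.

    The query structure (candidate-list lengths and relevant-set sizes) is
    held fixed; only the order is randomized.  Returns (mean, variance of a
    single MRR draw).
    """
    rng = rng or np.random.default_rng(0)
    queries = list(queries)
    draws = np.empty(n_samples)
    sizes = [(len(q.ranking), len(q.relevant & {p for p, _ in q.ranking})) for q in queries]
    for s in range(n_samples):
        rrs = []
        for n_cand, n_rel in sizes:
            if n_rel == 0:
                rrs.append(0.0)
                continue
            positions = rng.choice(n_cand, size=n_rel, replace=False)
            rrs.append(1.0 / (positions.min() + 1))
        draws[s] = np.mean(rrs)
    return float(draws.mean()), float(draws.var(ddof=1))


def top_pairs_table(score_fn, sequence: SnapshotSequence, age: int, k: int = 10,
                    catalog=None) -> pd.DataFrame:
    """The k highest-scoring unordered pairs at an age, flagged if already linked."""
    n = sequence.n_nodes
    all_pairs = list(itertools.combinations(range(n), 2))
    if k > len(all_pairs):
        import warnings
        warnings.warn(f"k={k} exceeds the {len(all_pairs)} available pairs; truncating")
        k = len(all_pairs)
    scores = np.asarray(score_fn(age, all_pairs), dtype=float)
    edges = sequence.snapshot_at(age).edge_set()
    order = sorted(range(len(all_pairs)), key=lambda m: (-scores[m], all_pairs[m]))
    rows = []
    for m in order[:k]:
        i, j = all_pairs[m]
        rows.append({
            "disease_i": catalog.names[i] if catalog else i,
            "disease_j": catalog.names[j] if catalog else j,
            "score": scores[m],
            "already_linked": (i, j) in edges,
        })
    return pd.DataFrame(rows)
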