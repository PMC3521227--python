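"""Weighted Spearman-footrule rank aggregation of per-dataset accuracies.

At a fixed feature-set size, each dataset contributes one ranked list of
methods (best balanced accuracy first) whose BA values double as weights.
The combined ranking is the permutation minimizing the summed weighted
footrule distance over all input lists, found by exhaustive enumeration
(6! = 720 candidates for six methods).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class RankedList:
    dataset: str
    methods: tuple[str, ...]  # best first
    weights: tuple[float, ...]  # aligned balanced accuracies

    def __post_init__(self) -> None:
        if len(self.methods) != len(set(self.methods)):
            raise ValueError(f"duplicate method in ranked list for {self.dataset!r}")
        if len(self.methods) != len(self.weights):
            raise ValueError("methods and weights must align")

    def ranks(self) -> dict[str, int]:
        return {m: i + 1 for i, m in enumerate(self.methods)}

    def normalized_weights(self) -> dict[str, float]:
        """Min-max normalized weights within the list; all-equal -> all 1."""
        w = np.asarray(self.weights, dtype=float)
        span = w.max() - w.min()
        if span == 0:
            return {m: 1.0 for m in self.methods}
        return {m: float((wi - w.min()) / span) for m, wi in zip(self.methods, w)}


@dataclass
class CombinedRanking:
    """Optimal permutation and objective value per feature-set size."""

    per_k: dict[int, tuple[tuple[str, ...], float]] = field(default_factory=dict)

    def average_ranks(self) -> pd.Series:
        """Mean combined-rank position of each method over the k values."""
        rows = {
            k: {m: i + 1 for i, m in enumerate(perm)} for k, (perm, _) in self.per_k.items()
        }
        return pd.DataFrame(rows).mean(axis=1).sort_values()


def accuracies_to_ranked_lists(table: pd.DataFrame) -> list[RankedList]:
    """One ranked list per dataset from a datasets x methods BA table.

    Ties in BA are broken by method tag ascending.
    """
    if table.isna().any().any():
        raise ValueError("missing balanced accuracy cell")
    lists = []
    for dataset, row in table.iterrows():
        order = sorted(row.index, key=lambda m: (-row[m], m))
        lists.append(RankedList(str(dataset), tuple(order), tuple(float(row[m]) for m in order)))
    return lists


def weighted_footrule(candidate: Sequence[str], rl: RankedList) -> float:
    """Sum over methods of W(x) * |rank_candidate(x) - rank_list(x)|.

    W is the method's balanced accuracy min-max normalized within the list,
    so equal accuracies reduce this to the unweighted Spearman footrule.
    """
    if set(candidate) != set(rl.methods):
        raise ValueError("candidate and list must cover the same methods")
    cr = {m: i + 1 for i, m in enumerate(candidate)}
    lr = rl.ranks()
    w = rl.normalized_weights()
    return float(sum(w[m] * abs(cr[m] - lr[m]) for m in rl.methods))


def brute_force_aggregate(lists: Iterable[RankedList]) -> tuple[tuple[str, ...], float]:
    """Exhaustively minimize the summed weighted footrule over permutations.

    Ties resolve to the lexicographically smallest permutation by method
    tag.  Guarded to at most 8 methods (factorial growth).
    """
    lists = list(lists)
    if not lists:
        raise ValueError("at least one ranked list required")
    methods = sorted(lists[0].methods)
    if not 2 <= len(methods) <= 8:
        raise ValueError("brute force supports 2..8 methods; use a heuristic search beyond that")
    best_perm: tuple[str, ...] | None = None
    best_phi = np.inf
    for perm in permutations(methods):  # lexicographic order over sorted tags
        phi = sum(weighted_footrule(perm, rl) for rl in lists)
        if phi < best_phi - 1e-12:
            best_phi, best_perm = phi, perm
    assert best_perm is not None
    return best_perm, float(best_phi)


def combine_over_k(results: pd.DataFrame) -> CombinedRanking:
    """Aggregate a tidy results table (method, dataset, k, balanced_accuracy)
    into a combined ranking per feature-set size."""
    combined = CombinedRanking()
    for k, chunk in results.groupby("k"):
        table = chunk.pivot(index="dataset", columns="method", values="balanced_accuracy")
        lists = accuracies_to_ranked_lists(table)
        combined.per_k[int(k)] = brute_force_aggregate(lists)
    return combined
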