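"""ReliefF and ordinal ReliefF (OReliefF) voxel ranking.

ReliefF scores each attribute ``A`` by how well its values separate patterns
that are close to each other: repeatedly pick a query pattern, find its ``k``
nearest neighbours of the same class (*hits*) and, for every other class, the
``k`` nearest of that class (*misses*), then update the quality ::

    Q[A] <- Q[A] - mean_hit diff(A)  +  sum_l  P(C_l)/(1 - P(C_q)) * mean_miss_l diff(A)

where ``diff(A, x1, x2) = |x1[A] - x2[A]|`` on raw values, the same
per-attribute term used (summed over attributes, i.e. Manhattan distance) for
the neighbour search.

OReliefF keeps the hit term and multiplies each class's miss contribution by
an ordinal penalty ``rho`` proportional to the label distance from the query
class (normalised to sum to 1 over the other classes), so disagreement with a
*far* class raises an attribute's quality more than disagreement with an
adjacent one.  With two classes the penalty is identically 1 and OReliefF
reduces exactly to ReliefF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ordivox.volumes import OrdinalDataset

__all__ = [
    "FeatureQuality",
    "diff",
    "ordinal_penalty",
    "nearest_hits_misses",
    "relieff",
    "orelieff",
    "select_top_fraction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureQuality:
    """Per-attribute quality weights produced by (O)ReliefF."""

    Q: np.ndarray
    k: int
    m: int
    seed: int | None
    method: str = "relieff"

    def __post_init__(self) -> None:
        object.__setattr__(self, "Q", np.asarray(self.Q, dtype=float))
        if not np.all(np.isfinite(self.Q)):
            raise ValueError("attribute qualities must be finite")

    @property
    def n_features(self) -> int:
        return self.Q.size

    def ranking(self) -> np.ndarray:
        """Feature columns ordered by descending quality, ties to lower index."""
        # stable sort on -Q keeps the lower index first among ties
        return np.argsort(-self.Q, kind="stable")


def diff(A: int, x1: np.ndarray, x2: np.ndarray) -> float:
    """Absolute difference of attribute ``A``'s raw values in two patterns."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return float(abs(x1[A] - x2[A]))


def ordinal_penalty(query_label: int, other_label: int, labels: np.ndarray | list[int]) -> float:
    """Ordinal penalty ``rho`` for a (query class, other class) pair.

    ``rho = |y_q - y_l| / sum_{l' != q} |y_q - y_l'|`` over the label set, so
    for a fixed query class the penalties of all other classes sum to 1 and
    grow with label distance.
    """
    labels = np.asarray(sorted(set(int(l) for l in labels)))
    query_label = int(query_label)
    other_label = int(other_label)
    if other_label == query_label:
        raise ValueError("ordinal penalty is defined only for a different class")
    if query_label not in labels or other_label not in labels:
        raise ValueError("labels must belong to the label set")
    denom = np.sum(np.abs(labels[labels != query_label] - query_label))
    return float(abs(other_label - query_label) / denom)


def nearest_hits_misses(
    dataset: OrdinalDataset, i: int, k: int
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Nearest hits and per-class nearest misses of pattern ``i``.

    Distance is Manhattan over all attributes; the query is excluded from the
    hits; ties at equal distance are broken by lower pattern index.  If a
    class has fewer than ``k`` available patterns, all of them are returned
    (the caller divides by the actual count); a class with no other members
    contributes nothing and is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X, y = dataset.X, dataset.y
    dist = np.abs(X - X[i]).sum(axis=1)
    # lexsort: primary key distance, secondary key index (deterministic ties)
    order = np.lexsort((np.arange(len(y)), dist))
    order = order[order != i]
    hits = order[y[order] == y[i]][:k]
    if hits.size == 0:
        logger.info("pattern %d is the only member of class %d: no hits", i, y[i])
    misses: dict[int, np.ndarray] = {}
    for l in range(dataset.L):
        if l == y[i]:
            continue
        cand = order[y[order] == l][:k]
        if cand.size == 0:
            logger.info("class %d has no patterns: contributes no misses", l)
            continue
        misses[l] = cand
    return hits, misses


def _relieff_core(
    dataset: OrdinalDataset,
    k: int,
    m: int | None,
    seed: int | None,
    ordinal: bool,
    queries: np.ndarray | None = None,
) -> FeatureQuality:
    if dataset.n_patterns == 0:
        raise ValueError("cannot run ReliefF on an empty dataset")
    present = np.flatnonzero(dataset.class_counts())
    if present.size < 2:
        raise ValueError("ReliefF needs at least two classes with patterns")
    if k < 1:
        raise ValueError("k must be >= 1")

    N = dataset.n_patterns
    if queries is None:
        if m is None:
            m = N
        if m < 1:
            raise ValueError("m must be >= 1")
        rng = np.random.default_rng(seed)
        if m <= N:
            queries = rng.permutation(N)[:m]
        else:
            queries = rng.integers(0, N, size=m)
    else:
        queries = np.asarray(queries, dtype=int)
        m = queries.size

    priors = dataset.class_priors
    label_set = np.arange(dataset.L)
    Q = np.zeros(dataset.n_features)
    for i in queries:
        hits, misses = nearest_hits_misses(dataset, int(i), k)
        if hits.size:
            Q -= np.abs(dataset.X[hits] - dataset.X[i]).mean(axis=0)
        q_label = dataset.y[i]
        weight_denom = 1.0 - priors[q_label]
        for l, idx in misses.items():
            w = priors[l] / weight_denom
            if ordinal:
                w *= ordinal_penalty(q_label, l, label_set)
            Q += w * np.abs(dataset.X[idx] - dataset.X[i]).mean(axis=0)
    method = "orelieff" if ordinal else "relieff"
    return FeatureQuality(Q=Q, k=k, m=int(m), seed=seed, method=method)


def relieff(
    dataset: OrdinalDataset,
    k: int = 5,
    m: int | None = None,
    seed: int | None = None,
    queries: np.ndarray | None = None,
) -> FeatureQuality:
    """Nominal ReliefF attribute quality.

    ``m`` defaults to the number of patterns ``N``; queries are sampled
    uniformly without replacement when ``m <= N`` (with replacement
    otherwise), or can be given explicitly for a shared random schedule.
    """
    return _relieff_core(dataset, k, m, seed, ordinal=False, queries=queries)


def orelieff(
    dataset: OrdinalDataset,
    k: int = 5,
    m: int | None = None,
    seed: int | None = None,
    queries: np.ndarray | None = None,
) -> FeatureQuality:
    """Ordinal ReliefF: ReliefF with the label-distance miss penalty."""
    return _relieff_core(dataset, k, m, seed, ordinal=True, queries=queries)


def select_top_fraction(quality: FeatureQuality, p: float) -> np.ndarray:
    """The ``floor(p * S)`` highest-quality feature columns, descending by Q.

    Ties are broken toward the lower feature index.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("fraction p must lie in (0, 1]")
    n = int(np.floor(p * quality.n_features))
    return quality.ranking()[:n]
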