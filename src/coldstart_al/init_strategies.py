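"""Label-free initialization query strategies for cold-start active learning.

Four ways to spend the initial annotation budget before any label exists:

* ``diversity_init`` — K-means with k = budget over (standardized)
  embeddings; the member nearest each centroid is queried.
* ``uncertainty_init`` — trains a proxy regressor from images to frozen
  embeddings on the whole unlabeled pool and queries the samples with the
  largest MC-dropout inference variance.
* ``hybrid_init`` — two steps: cluster as in diversity, then take the
  highest-variance member of each cluster.
* ``random_init`` — replicated uniform draws, nested across budgets within
  each replicate so higher budgets contain lower ones.

All ties (equal distance, equal variance) break toward the smallest id so
selections are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .encoders import EmbeddingMatrix, standardize_embeddings
from .models import TrainingConfig, ESTIMATOR_CONFIG, UncertaintyEstimator, train_uncertainty_estimator

__all__ = [
    "MCDropoutConfig",
    "UncertaintyScores",
    "QueryResult",
    "diversity_init",
    "mc_dropout_variance",
    "uncertainty_init",
    "hybrid_init",
    "random_init",
    "save_query_results",
]

_KMEANS_RESTARTS = 10
_EMPTY_CLUSTER_RETRIES = 5


@dataclass(frozen=True)
class MCDropoutConfig:
    """T stochastic passes at dropout probability P, variance per dimension.

    The per-dimension population variance (divide by T, not T-1) follows
    the benchmark's printed formula; ``aggregation`` collapses the vector
    of per-dimension variances to one scalar score per sample.
    """

    n_passes: int = 100
    dropout_probability: float = 0.5
    seed: int = 0
    aggregation: str = "mean_over_dims"

    def __post_init__(self) -> None:
        if self.n_passes < 1:
            raise ValueError(f"n_passes must be >= 1, got {self.n_passes}")
        if not 0.0 <= self.dropout_probability < 1.0:
            raise ValueError("dropout_probability must be in [0, 1)")
        if self.aggregation not in ("mean_over_dims", "sum_over_dims"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class UncertaintyScores:
    ids: list[str]
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.variance = np.asarray(self.variance, dtype=float)
        if self.variance.shape[0] != len(self.ids):
            raise ValueError("variance length must match ids")
        if np.any(self.variance < -1e-12):
            raise ValueError("variances must be nonnegative")
        self.variance = np.maximum(self.variance, 0.0)


@dataclass
class QueryResult:
    selected_ids: list[str]
    strategy: str
    budget: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selected_ids)) != len(self.selected_ids):
            raise ValueError("selected ids must be unique")
        if len(self.selected_ids) != self.budget:
            raise ValueError(
                f"selection size ({len(self.selected_ids)}) must equal budget ({self.budget})"
            )


def _fit_kmeans(vectors: np.ndarray, k: int, seed: int) -> KMeans:
    """K-means++ with restarts; reseeds on the (rare) empty cluster.

    Tiny pools get extra restarts — they cost nothing and make the
    partition reliably the global SSE optimum.
    """
    n_init = 50 if vectors.shape[0] <= 64 else _KMEANS_RESTARTS
    for attempt in range(_EMPTY_CLUSTER_RETRIES):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + attempt)
        labels = km.fit_predict(vectors)
        if np.unique(labels).size == k:
            return km
    raise RuntimeError(f"K-means produced an empty cluster in {_EMPTY_CLUSTER_RETRIES} attempts")


def _cluster(embeddings: EmbeddingMatrix, budget: int, seed: int, standardize: bool) -> tuple[np.ndarray, np.ndarray]:
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if budget > len(embeddings):
        raise ValueError(f"budget ({budget}) exceeds pool size ({len(embeddings)})")
    em = standardize_embeddings(embeddings) if standardize else embeddings
    km = _fit_kmeans(em.vectors, budget, seed)
    return km.labels_, km.cluster_centers_


def diversity_init(
    embeddings: EmbeddingMatrix, budget: int, seed: int = 0, standardize: bool = True
) -> QueryResult:
    """K-means with k = budget; query each cluster's nearest-to-centroid member."""
    labels, _ = _cluster(embeddings, budget, seed, standardize)
    em = standardize_embeddings(embeddings) if standardize else embeddings
    ids = np.asarray(em.ids)
    selected: list[str] = []
    for c in range(budget):
        members = np.flatnonzero(labels == c)
        centroid = em.vectors[members].mean(axis=0)  # exact cluster mean
        dist = np.linalg.norm(em.vectors[members] - centroid, axis=1)
        # ties -> smallest id
        order = sorted(range(members.size), key=lambda i: (dist[i], ids[members[i]]))
        selected.append(str(ids[members[order[0]]]))
    return QueryResult(
        selected_ids=selected,
        strategy="diversity",
        budget=budget,
        diagnostics={"cluster_labels": labels.tolist()},
    )


def mc_dropout_variance(
    estimator: UncertaintyEstimator,
    images: np.ndarray,
    config: MCDropoutConfig,
    ids: list[str] | None = None,
) -> UncertaintyScores:
    """Per-sample aggregated inference variance over T stochastic passes.

    Each pass re-draws the dropout pattern at probability P; the variance
    per output dimension is the population variance over the T outputs
    (1/T normalization), then aggregated across dimensions.

    ``estimator`` may be any object with a
    ``mc_forward(images, dropout_p, rng) -> (n, d)`` method.
    """
    rng = np.random.default_rng(config.seed)
    passes = np.stack(
        [estimator.mc_forward(images, config.dropout_probability, rng) for _ in range(config.n_passes)]
    )  # (T, n, d)
    per_dim_var = passes.var(axis=0, ddof=0)  # divide by T, per the formula
    if config.aggregation == "mean_over_dims":
        variance = per_dim_var.mean(axis=1)
    else:
        variance = per_dim_var.sum(axis=1)
    if ids is None:
        ids = [f"i{j}" for j in range(variance.shape[0])]
    return UncertaintyScores(ids=list(ids), variance=variance)


def _top_by_variance(scores: UncertaintyScores, budget: int) -> list[str]:
    order = sorted(range(len(scores.ids)), key=lambda i: (-scores.variance[i], scores.ids[i]))
    return [scores.ids[i] for i in order[:budget]]


def uncertainty_init(
    pool_images: np.ndarray,
    embeddings: EmbeddingMatrix,
    budget: int,
    train_config: TrainingConfig = ESTIMATOR_CONFIG,
    mc_config: MCDropoutConfig = MCDropoutConfig(),
    scores: UncertaintyScores | None = None,
) -> QueryResult:
    """Proxy-task uncertainty: largest MC-dropout variance wins the budget.

    The estimator is trained on the full unlabeled pool (the only data
    available before annotation). Precomputed ``scores`` may be injected,
    e.g. to share one estimator across budgets.
    """
    if budget > len(embeddings):
        raise ValueError(f"budget ({budget}) exceeds pool size ({len(embeddings)})")
    if scores is None:
        estimator, _ = train_uncertainty_estimator(pool_images, embeddings, train_config)
        scores = mc_dropout_variance(estimator, pool_images, mc_config, ids=embeddings.ids)
    selected = _top_by_variance(scores, budget)
    return QueryResult(
        selected_ids=selected,
        strategy="uncertainty",
        budget=budget,
        diagnostics={"variance": dict(zip(scores.ids, scores.variance.tolist()))},
    )


def hybrid_init(
    pool_images: np.ndarray,
    embeddings: EmbeddingMatrix,
    budget: int,
    train_config: TrainingConfig = ESTIMATOR_CONFIG,
    mc_config: MCDropoutConfig = MCDropoutConfig(),
    seed: int = 0,
    standardize: bool = True,
    scores: UncertaintyScores | None = None,
) -> QueryResult:
    """Two-step hybrid: cluster for diversity, then the most uncertain per cluster."""
    labels, _ = _cluster(embeddings, budget, seed, standardize)
    if scores is None:
        estimator, _ = train_uncertainty_estimator(pool_images, embeddings, train_config)
        scores = mc_dropout_variance(estimator, pool_images, mc_config, ids=embeddings.ids)
    if list(scores.ids) != list(embeddings.ids):
        scores = UncertaintyScores(
            ids=list(embeddings.ids),
            variance=np.array([dict(zip(scores.ids, scores.variance))[s] for s in embeddings.ids]),
        )
    ids = np.asarray(embeddings.ids)
    selected: list[str] = []
    for c in range(budget):
        members = np.flatnonzero(labels == c)
        order = sorted(members.tolist(), key=lambda i: (-scores.variance[i], ids[i]))
        selected.append(str(ids[order[0]]))
    return QueryResult(
        selected_ids=selected,
        strategy="hybrid",
        budget=budget,
        diagnostics={"cluster_labels": labels.tolist()},
    )


def random_init(
    pool_ids: list[str],
    budgets: list[int],
    n_reps: int = 100,
    seed: int = 0,
) -> list[dict[int, QueryResult]]:
    """Replicated nested random baselines.

    Each replicate draws one permutation of the pool; the budget-b set is
    its first b elements, so within a replicate every higher-budget set
    contains every lower-budget set.
    """
    budgets = sorted(budgets)
    if budgets[0] < 1:
        raise ValueError("budgets must be >= 1")
    if budgets[-1] > len(pool_ids):
        raise ValueError(f"largest budget ({budgets[-1]}) exceeds pool size ({len(pool_ids)})")
    rng = np.random.default_rng(seed)
    reps: list[dict[int, QueryResult]] = []
    for rep in range(n_reps):
        perm = rng.permutation(len(pool_ids))
        ordered = [pool_ids[i] for i in perm]
        reps.append(
            {
                b: QueryResult(
                    selected_ids=ordered[:b],
                    strategy="random",
                    budget=b,
                    diagnostics={"rep": rep},
                )
                for b in budgets
            }
        )
    return reps


def save_query_results(results: list[QueryResult], path: str | Path, seed: int | None = None) -> None:
    records = [
        {
            "strategy": r.strategy,
            "budget": r.budget,
            "seed": seed,
            "selected_ids": r.selected_ids,
            "diagnostics": r.diagnostics,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(records, indent=1))
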