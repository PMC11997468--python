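"""The pool-based active-learning loop: budgets, oracle, and warm-phase querying.

A run starts from an empty labeled set, spends an initial budget N0 with a
label-free strategy, then performs k iterations of N1 annotations each
(total budget B = N0 + k N1). The warm phase queries by classifier
uncertainty — in binary classification, least confidence, margin of
confidence and entropy all reduce to "predictive probability nearest
0.5", so one rule serves all three — or uniformly at random as baseline.
After every annotation batch the classifier is retrained (from scratch by
default) on the accumulated labeled set and evaluated on the held-out
test set; the test set is never used for training or stopping.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .datasets import ImageDataset
from .encoders import EncoderModel, encode
from .evaluation import MetricEstimate, bootstrap_sd
from .init_strategies import (
    MCDropoutConfig,
    QueryResult,
    UncertaintyScores,
    diversity_init,
    hybrid_init,
    uncertainty_init,
)
from .models import (
    ESTIMATOR_CONFIG,
    EmbeddingClassifier,
    ImageClassifier,
    TrainingConfig,
    predict_proba,
    train_classifier,
)

__all__ = [
    "BudgetSchedule",
    "PoolState",
    "Oracle",
    "Checkpoint",
    "ALRunRecord",
    "uncertainty_scores",
    "uncertainty_query",
    "run_al",
    "run_all_samples",
    "sub_seed",
]


def sub_seed(master: int, *tags) -> int:
    """Deterministic fan-out of a master seed to component seeds (< 2^31)."""
    digest = hashlib.blake2b(
        ("/".join([str(master)] + [str(t) for t in tags])).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass(frozen=True)
class BudgetSchedule:
    initial_budget: int
    per_iteration_budget: int = 0
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.initial_budget < 1:
            raise ValueError("initial_budget must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.n_iterations >= 1 and self.per_iteration_budget < 1:
            raise ValueError("per_iteration_budget must be >= 1 when iterating")

    @property
    def total(self) -> int:
        return self.initial_budget + self.n_iterations * self.per_iteration_budget


@dataclass
class PoolState:
    unlabeled_ids: set[str]
    labeled: list[tuple[str, int]] = field(default_factory=list)
    iteration: int = 0

    @property
    def budget_spent(self) -> int:
        return len(self.labeled)

    @property
    def labeled_ids(self) -> list[str]:
        return [sid for sid, _ in self.labeled]

    def annotate(self, pairs: list[tuple[str, int]]) -> None:
        for sid, _ in pairs:
            if sid not in self.unlabeled_ids:
                raise ValueError(f"sample {sid!r} is not in the unlabeled pool")
        self.unlabeled_ids.difference_update(sid for sid, _ in pairs)
        self.labeled.extend(pairs)


class Oracle:
    """Simulated annotator: consistent answers from a hidden label table."""

    def __init__(self, labels: dict[str, int]) -> None:
        self._labels = dict(labels)
        self._annotated: set[str] = set()

    def annotate(self, ids: list[str]) -> list[tuple[str, int]]:
        missing = [s for s in ids if s not in self._labels]
        if missing:
            raise KeyError(f"oracle has no labels for {missing[:3]}")
        self._annotated.update(ids)
        return [(s, self._labels[s]) for s in ids]

    @property
    def query_count(self) -> int:
        return len(self._annotated)


@dataclass
class Checkpoint:
    stage: str  # "initialization" | "subsequent"
    iteration: int
    budget: int
    newly_selected: list[str]
    labeled_ids: list[str]
    minority_proportion: float
    metrics: dict[str, MetricEstimate]


@dataclass
class ALRunRecord:
    init_strategy: str
    subsequent_strategy: str
    encoder_name: str
    backbone: str
    schedule: BudgetSchedule
    seed: int
    checkpoints: list[Checkpoint] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (BudgetSchedule, Checkpoint, MetricEstimate)):
                return asdict(o)
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(asdict(self), indent=1, default=default))


@dataclass
class BinaryUncertainty:
    least_confidence: np.ndarray
    margin: np.ndarray
    entropy: np.ndarray


def uncertainty_scores(probabilities) -> BinaryUncertainty:
    """The three classic uncertainty scores of a positive-class probability.

    least_confidence = max(p, 1-p) (low is uncertain), margin = |2p - 1|
    (low is uncertain), entropy = -p log p - (1-p) log(1-p) (high is
    uncertain); all three peak in uncertainty at p = 0.5.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log(p), 0.0) - np.where(p < 1, (1 - p) * np.log(1 - p), 0.0)
    return BinaryUncertainty(
        least_confidence=np.maximum(p, 1 - p),
        margin=np.abs(2 * p - 1),
        entropy=ent,
    )


def uncertainty_query(ids: list[str], p_positive: np.ndarray, batch: int) -> QueryResult:
    """Select the ``batch`` samples with probability nearest 0.5; ties by id."""
    p = np.asarray(p_positive, dtype=float)
    if batch > len(ids):
        raise ValueError(f"batch ({batch}) exceeds pool size ({len(ids)})")
    order = sorted(range(len(ids)), key=lambda i: (abs(p[i] - 0.5), ids[i]))
    return QueryResult(
        selected_ids=[ids[i] for i in order[:batch]],
        strategy="uncertainty",
        budget=batch,
        diagnostics={"p_positive": {ids[i]: float(p[i]) for i in order[:batch]}},
    )


def _make_classifier(backbone: str, train_pool: ImageDataset, embedding_dim: int | None):
    if backbone == "image":
        h, w = train_pool.images.shape[1:]
        return ImageClassifier(image_height=h, image_width=w)
    if backbone == "embedding":
        return EmbeddingClassifier(input_dim=embedding_dim)
    raise ValueError(f"unknown backbone {backbone!r}")


def _evaluate(model, test_inputs, test_labels, n_boot: int, seed: int) -> dict[str, MetricEstimate]:
    scores = predict_proba(model, test_inputs)[:, 1]
    return {
        "auroc": bootstrap_sd(test_labels, scores, "auroc", n_boot=n_boot, seed=seed),
        "auprc": bootstrap_sd(test_labels, scores, "auprc", n_boot=n_boot, seed=seed),
    }


def run_al(
    train_pool: ImageDataset,
    test_set: ImageDataset,
    encoder: EncoderModel | None,
    init_strategy: str | QueryResult,
    subsequent_strategy: str,
    schedule: BudgetSchedule,
    backbone: str = "image",
    train_config: TrainingConfig = TrainingConfig(),
    estimator_config: TrainingConfig = ESTIMATOR_CONFIG,
    mc_config: MCDropoutConfig = MCDropoutConfig(),
    seed: int = 0,
    retrain: str = "scratch",
    n_boot: int = 1000,
    init_scores: UncertaintyScores | None = None,
) -> ALRunRecord:
    """One full cold-start AL run with a test-set checkpoint per budget level."""
    if schedule.total > len(train_pool):
        raise ValueError(
            f"schedule total ({schedule.total}) exceeds pool size ({len(train_pool)})"
        )
    if subsequent_strategy not in ("uncertainty", "random"):
        raise ValueError(f"unknown subsequent strategy {subsequent_strategy!r}")
    if retrain not in ("scratch", "continue"):
        raise ValueError(f"unknown retrain mode {retrain!r}")

    rng = np.random.default_rng(sub_seed(seed, "al_loop"))
    needs_embeddings = backbone == "embedding" or (
        isinstance(init_strategy, str) and init_strategy in ("diversity", "uncertainty", "hybrid")
    )
    train_emb = test_emb = None
    if needs_embeddings:
        if encoder is None:
            raise ValueError("an encoder is required for embedding-based strategies/backbones")
        train_emb = encode(encoder, train_pool)
        if backbone == "embedding":
            test_emb = encode(encoder, test_set)

    # label-free initialization
    if isinstance(init_strategy, QueryResult):
        init_result = init_strategy
    elif init_strategy == "diversity":
        init_result = diversity_init(train_emb, schedule.initial_budget, seed=sub_seed(seed, "kmeans"))
    elif init_strategy == "uncertainty":
        init_result = uncertainty_init(
            train_pool.images, train_emb, schedule.initial_budget,
            replace(estimator_config, seed=sub_seed(seed, "estimator")),
            replace(mc_config, seed=sub_seed(seed, "mc")),
            scores=init_scores,
        )
    elif init_strategy == "hybrid":
        init_result = hybrid_init(
            train_pool.images, train_emb, schedule.initial_budget,
            replace(estimator_config, seed=sub_seed(seed, "estimator")),
            replace(mc_config, seed=sub_seed(seed, "mc")),
            seed=sub_seed(seed, "kmeans"),
            scores=init_scores,
        )
    elif init_strategy == "random":
        perm = rng.permutation(len(train_pool.ids))
        init_result = QueryResult(
            selected_ids=[train_pool.ids[i] for i in perm[: schedule.initial_budget]],
            strategy="random",
            budget=schedule.initial_budget,
        )
    else:
        raise ValueError(f"unknown init strategy {init_strategy!r}")

    oracle = Oracle(dict(zip(train_pool.ids, train_pool.labels.tolist())))
    pool = PoolState(unlabeled_ids=set(train_pool.ids))
    pool.annotate(oracle.annotate(init_result.selected_ids))

    counts = np.bincount(train_pool.labels, minlength=2)
    minority_label = int(np.argmin(counts))
    id_index = {s: i for i, s in enumerate(train_pool.ids)}

    def inputs_for(ids: list[str]) -> np.ndarray:
        if backbone == "image":
            return train_pool.images[[id_index[s] for s in ids]]
        return train_emb.subset_by_ids(ids).vectors

    test_inputs = test_set.images if backbone == "image" else test_emb.vectors
    model = _make_classifier(backbone, train_pool, None if train_emb is None else train_emb.embedding_dim)
    cfg = replace(train_config, seed=sub_seed(seed, "train"))

    record = ALRunRecord(
        init_strategy=init_result.strategy,
        subsequent_strategy=subsequent_strategy,
        encoder_name=encoder.name if encoder is not None else "none",
        backbone=backbone,
        schedule=schedule,
        seed=seed,
    )

    def checkpoint(stage: str, newly: list[str]) -> None:
        labels = np.array([y for _, y in pool.labeled])
        train_classifier(model, inputs_for(pool.labeled_ids), labels, cfg,
                         warm_start=(retrain == "continue"))
        metrics = _evaluate(model, test_inputs, test_set.labels, n_boot, sub_seed(seed, "boot", pool.iteration))
        init_labels = np.array([y for _, y in pool.labeled[: schedule.initial_budget]])
        record.checkpoints.append(
            Checkpoint(
                stage=stage,
                iteration=pool.iteration,
                budget=pool.budget_spent,
                newly_selected=list(newly),
                labeled_ids=pool.labeled_ids,
                minority_proportion=float(np.mean(init_labels == minority_label)),
                metrics=metrics,
            )
        )

    checkpoint("initialization", init_result.selected_ids)

    for _ in range(schedule.n_iterations):
        pool.iteration += 1
        unlabeled = sorted(pool.unlabeled_ids)
        if subsequent_strategy == "uncertainty":
            p = predict_proba(model, inputs_for(unlabeled))[:, 1]
            query = uncertainty_query(unlabeled, p, schedule.per_iteration_budget)
        else:
            pick = rng.permutation(len(unlabeled))[: schedule.per_iteration_budget]
            query = QueryResult(
                selected_ids=[unlabeled[i] for i in pick],
                strategy="random",
                budget=schedule.per_iteration_budget,
            )
        pool.annotate(oracle.annotate(query.selected_ids))
        checkpoint("subsequent", query.selected_ids)

    return record


def run_all_samples(
    train_pool: ImageDataset,
    test_set: ImageDataset,
    encoder: EncoderModel | None = None,
    backbone: str = "image",
    train_config: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    n_boot: int = 1000,
) -> ALRunRecord:
    """Upper-bound run: every pool sample annotated, one checkpoint."""
    schedule = BudgetSchedule(initial_budget=len(train_pool))
    full = QueryResult(selected_ids=list(train_pool.ids), strategy="all_samples",
                       budget=len(train_pool))
    return run_al(
        train_pool, test_set, encoder, full, "uncertainty", schedule,
        backbone=backbone, train_config=train_config, seed=seed, n_boot=n_boot,
    )
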