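"""AUROC / AUPRC point estimates with nonparametric-bootstrap SDs.

AUROC uses the rank (Mann-Whitney) formulation — the probability that a
random positive outscores a random negative, ties counted half; AUPRC is
the step-wise average-precision rule. Both are chosen over
threshold-based metrics because the benchmark's cohorts are heavily
imbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricEstimate", "auroc", "auprc", "bootstrap_sd"]

DEFAULT_N_BOOT = 1000
_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class MetricEstimate:
    metric: str
    mean: float
    bootstrap_sd: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("metric mean must be in [0, 1]")
        if self.bootstrap_sd < 0:
            raise ValueError("bootstrap sd must be nonnegative")


def _check(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    return labels, scores


def auroc(labels, scores) -> float:
    """Rank-based AUROC; undefined (raises) unless both classes are present."""
    labels, scores = _check(labels, scores)
    if np.unique(labels).size < 2:
        raise ValueError("AUROC is undefined on single-class labels")
    return float(np.clip(roc_auc_score(labels, scores), 0.0, 1.0))


def auprc(labels, scores) -> float:
    """Average-precision AUPRC; requires at least one positive."""
    labels, scores = _check(labels, scores)
    if labels.sum() == 0:
        raise ValueError("AUPRC is undefined without positives")
    return float(np.clip(average_precision_score(labels, scores), 0.0, 1.0))


_METRICS: dict[str, Callable] = {"auroc": auroc, "auprc": auprc}


def bootstrap_sd(
    labels,
    scores,
    metric: str | Callable = "auroc",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MetricEstimate:
    """Point estimate plus SD over ``n_boot`` bootstrap resamples.

    Test indices are resampled with replacement; resamples that lose a
    class are redrawn so every replicate is an effective one. ``metric``
    may be a name or any callable ``(labels, scores) -> float``.
    """
    labels, scores = _check(labels, scores)
    fn = _METRICS[metric] if isinstance(metric, str) else metric
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "custom")
    point = fn(labels, scores)  # raises if undefined on the full sample
    rng = np.random.default_rng(seed)
    n = labels.size
    values = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(_MAX_REDRAWS):
            idx = rng.integers(0, n, size=n)
            if np.unique(labels[idx]).size == 2:
                break
        else:  # pragma: no cover - requires a pathological sample
            raise RuntimeError("could not draw a two-class bootstrap resample")
        values[b] = fn(labels[idx], scores[idx])
    sd = float(values.std(ddof=1)) if n_boot > 1 else 0.0
    return MetricEstimate(metric=name, mean=float(point), bootstrap_sd=sd, n_boot=n_boot, seed=seed)
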