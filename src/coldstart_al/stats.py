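"""Statistical comparison protocol over collections of AL run results.

Five analyses, each consuming a tidy results table (one row per run x
checkpoint x metric) and emitting one test record per cell:

1. encoder arms (domain-specific vs general) — paired t, "greater";
2. classifier backbones (embedding MLP vs pixel CNN) — paired t, "less";
3. initialization vs subsequent performance — Pearson, "greater";
4. one-shot initialization vs the full AL cycle at equal total budget —
   paired t, "less";
5. minority-class proportion of the initialization sample vs
   performance — Pearson, "greater".

Directional alternatives follow the benchmark's stated hypotheses; every
test is also available two-sided. Raw p-values are reported per cell with
no multiple-testing correction. The pairing unit for the paired tests is
the matched (strategy x budget)-style cell within a dataset, with
replicates averaged first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TIDY_COLUMNS",
    "StatTestResult",
    "ZeroVarianceError",
    "paired_t_test",
    "pearson_test",
    "compare_encoders",
    "compare_backbones",
    "init_vs_subsequent_correlation",
    "oneshot_vs_full",
    "class_balance_correlation",
    "results_frame",
]

#: schema of the tidy results table the analyses consume
TIDY_COLUMNS = [
    "run_id", "dataset", "encoder", "strategy", "backbone",
    "stage", "budget", "rep", "metric", "value", "sd", "minority_prop",
]

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


class ZeroVarianceError(ValueError):
    """The test statistic is degenerate (zero-variance input)."""


@dataclass(frozen=True)
class StatTestResult:
    test: str
    alternative: str
    statistic: float
    p_value: float
    n_pairs: int
    metric: str
    grouping: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must be in [0, 1]")
        if self.n_pairs < 3:
            raise ValueError("a reported test needs at least 3 pairs")


def _check_alt(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    return _ALTERNATIVES[alternative]


def paired_t_test(a, b, alternative: str = "two_sided",
                  metric: str = "", grouping: str = "") -> StatTestResult:
    """Classic paired t on the differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    if a.size < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    d = a - b
    if np.allclose(d, d[0]):
        raise ZeroVarianceError("differences have zero variance")
    res = sps.ttest_rel(a, b, alternative=_check_alt(alternative))
    return StatTestResult(
        test="paired_t", alternative=alternative, statistic=float(res.statistic),
        p_value=float(res.pvalue), n_pairs=a.size, metric=metric, grouping=grouping,
    )


def pearson_test(x, y, alternative: str = "two_sided",
                 metric: str = "", grouping: str = "") -> StatTestResult:
    """Pearson correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("Pearson test needs at least 3 observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ZeroVarianceError("zero variance in an input vector")
    res = sps.pearsonr(x, y, alternative=_check_alt(alternative))
    return StatTestResult(
        test="pearson", alternative=alternative, statistic=float(res.statistic),
        p_value=float(res.pvalue), n_pairs=x.size, metric=metric, grouping=grouping,
    )


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results table lacks columns: {missing}")
    return df


def _cell_means(df: pd.DataFrame, keys: list[str]) -> pd.Series:
    return df.groupby(keys, dropna=False)["value"].mean()


def compare_encoders(
    df: pd.DataFrame,
    pairs: list[tuple[str, str]],
    metrics: tuple[str, ...] = ("auroc", "auprc"),
    alternative: str = "greater",
) -> list[StatTestResult]:
    """Per (dataset, encoder pair, stage, metric): is the first arm better?

    Cells are matched (strategy, budget, backbone) combinations; replicate
    runs are averaged within each cell before pairing.
    """
    df = _validate_frame(df)
    results = []
    for dataset in sorted(df["dataset"].unique()):
        for enc_a, enc_b in pairs:
            for stage in sorted(df["stage"].unique()):
                sub = df[(df["dataset"] == dataset) & (df["stage"] == stage)]
                for metric in metrics:
                    m = sub[sub["metric"] == metric]
                    a = _cell_means(m[m["encoder"] == enc_a], ["strategy", "budget", "backbone"])
                    b = _cell_means(m[m["encoder"] == enc_b], ["strategy", "budget", "backbone"])
                    common = a.index.intersection(b.index)
                    if len(common) == 0:
                        raise ValueError(
                            f"no matched cells for encoders {enc_a!r}/{enc_b!r} in {dataset}/{stage}"
                        )
                    results.append(
                        paired_t_test(
                            a.loc[common].to_numpy(), b.loc[common].to_numpy(), alternative,
                            metric=metric,
                            grouping=f"dataset={dataset}|pair={enc_a}>{enc_b}|stage={stage}",
                        )
                    )
    return results


def compare_backbones(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = ("auroc", "auprc"),
    alternative: str = "less",
) -> list[StatTestResult]:
    """Per (dataset, encoder, stage, metric): embedding MLP vs pixel classifier.

    The default alternative "less" asks whether the representation-based
    classifier underperforms the pixel-based one.
    """
    df = _validate_frame(df)
    results = []
    for dataset in sorted(df["dataset"].unique()):
        for encoder in sorted(df[df["backbone"] == "embedding"]["encoder"].unique()):
            for stage in sorted(df["stage"].unique()):
                sub = df[(df["dataset"] == dataset) & (df["stage"] == stage)]
                for metric in metrics:
                    m = sub[sub["metric"] == metric]
                    a = _cell_means(
                        m[(m["backbone"] == "embedding") & (m["encoder"] == encoder)],
                        ["strategy", "budget"],
                    )
                    b = _cell_means(m[m["backbone"] == "image"], ["strategy", "budget"])
                    common = a.index.intersection(b.index)
                    if len(common) == 0:
                        raise ValueError(
                            f"no matched cells for backbones in {dataset}/{encoder}/{stage}"
                        )
                    results.append(
                        paired_t_test(
                            a.loc[common].to_numpy(), b.loc[common].to_numpy(), alternative,
                            metric=metric,
                            grouping=f"dataset={dataset}|encoder={encoder}|stage={stage}",
                        )
                    )
    return results


def init_vs_subsequent_correlation(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = ("auroc", "auprc"),
    alternative: str = "greater",
) -> list[StatTestResult]:
    """Per (dataset, overall budget, metric): does a good start predict a good end?

    Correlates, across runs, the initialization-checkpoint value with the
    subsequent-stage value at each overall budget.
    """
    df = _validate_frame(df)
    results = []
    for dataset in sorted(df["dataset"].unique()):
        sub = df[df["dataset"] == dataset]
        for metric in metrics:
            m = sub[sub["metric"] == metric]
            init = m[m["stage"] == "initialization"].set_index("run_id")["value"]
            subsequent = m[m["stage"] == "subsequent"]
            for budget in sorted(subsequent["budget"].unique()):
                later = subsequent[subsequent["budget"] == budget].set_index("run_id")["value"]
                common = init.index.intersection(later.index)
                if len(common) < 3:
                    raise ValueError(
                        f"fewer than 3 paired runs for {dataset}/budget={budget}/{metric}"
                    )
                results.append(
                    pearson_test(
                        init.loc[common].to_numpy(), later.loc[common].to_numpy(), alternative,
                        metric=metric, grouping=f"dataset={dataset}|budget={budget}",
                    )
                )
    return results


def oneshot_vs_full(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = ("auroc", "auprc"),
    alternative: str = "less",
) -> list[StatTestResult]:
    """Per (dataset, total budget, metric): one-shot initialization vs full AL.

    One-shot arms are initialization-stage rows at the total budget; full
    arms are subsequent-stage rows at the same total. Cells are matched
    (encoder, strategy, backbone) combinations, replicates averaged first.
    """
    df = _validate_frame(df)
    results = []
    oneshot = df[df["stage"] == "initialization"]
    full = df[df["stage"] == "subsequent"]
    for dataset in sorted(df["dataset"].unique()):
        budgets = sorted(
            set(oneshot[oneshot["dataset"] == dataset]["budget"])
            & set(full[full["dataset"] == dataset]["budget"])
        )
        if not budgets:
            raise ValueError(f"no matched total budgets for dataset {dataset!r}")
        for budget in budgets:
            for metric in metrics:
                a = _cell_means(
                    oneshot[(oneshot["dataset"] == dataset) & (oneshot["budget"] == budget)
                            & (oneshot["metric"] == metric)],
                    ["encoder", "strategy", "backbone"],
                )
                b = _cell_means(
                    full[(full["dataset"] == dataset) & (full["budget"] == budget)
                         & (full["metric"] == metric)],
                    ["encoder", "strategy", "backbone"],
                )
                common = a.index.intersection(b.index)
                if len(common) == 0:
                    raise ValueError(f"unmatched budget cells at {dataset}/budget={budget}")
                results.append(
                    paired_t_test(
                        a.loc[common].to_numpy(), b.loc[common].to_numpy(), alternative,
                        metric=metric, grouping=f"dataset={dataset}|budget={budget}",
                    )
                )
    return results


def class_balance_correlation(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = ("auroc", "auprc"),
    alternative: str = "greater",
) -> list[StatTestResult]:
    """Per (dataset, stage, budget, metric): minority share vs performance.

    Output rows are ordered by budget within each stage so budget-dependent
    (e.g. U-shaped) p-value patterns can be read off directly.
    """
    df = _validate_frame(df)
    results = []
    for dataset in sorted(df["dataset"].unique()):
        for stage in sorted(df[df["dataset"] == dataset]["stage"].unique()):
            sub = df[(df["dataset"] == dataset) & (df["stage"] == stage)]
            for budget in sorted(sub["budget"].unique()):
                cell = sub[sub["budget"] == budget]
                for metric in metrics:
                    m = cell[cell["metric"] == metric]
                    if len(m) < 3:
                        raise ValueError(
                            f"fewer than 3 runs in cell {dataset}/{stage}/budget={budget}"
                        )
                    results.append(
                        pearson_test(
                            m["minority_prop"].to_numpy(), m["value"].to_numpy(), alternative,
                            metric=metric,
                            grouping=f"dataset={dataset}|stage={stage}|budget={budget}",
                        )
                    )
    return results


def results_frame(results: list[StatTestResult]) -> pd.DataFrame:
    """Flatten test records into a table mirroring the analysis summaries."""
    return pd.DataFrame(
        [
            {
                "grouping": r.grouping, "metric": r.metric, "test": r.test,
                "alternative": r.alternative, "statistic": r.statistic,
                "p_value": r.p_value, "n_pairs": r.n_pairs,
            }
            for r in results
        ]
    )
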