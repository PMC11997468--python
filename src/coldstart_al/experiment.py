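"""Config-driven orchestration of the full benchmark grid.

One experiment = one synthetic cohort, a set of frozen encoders, the four
initialization strategies over a budget grid, full AL runs under the
N0 + k x N1 schedule, the all-samples upper bound, and nested random
baselines — all fanned out deterministically from a single master seed.
Outputs are a tidy results CSV (one row per run x checkpoint x metric),
per-run JSON records, and aggregated curve data.

Seed fan-out: every component seed is ``sub_seed(master_seed, *tags)``
where the tags name the component (e.g. ``("run", encoder, strategy,
backbone, rep)``), so any subset of the grid can be reproduced in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import pandas as pd
import yaml

from .al_loop import ALRunRecord, BudgetSchedule, run_al, run_all_samples, sub_seed
from .datasets import generate_dataset, preset, stratified_split
from .encoders import encode, make_encoder
from .init_strategies import MCDropoutConfig, mc_dropout_variance, random_init
from .models import ESTIMATOR_CONFIG, TrainingConfig, train_uncertainty_estimator
from .stats import TIDY_COLUMNS

__all__ = ["ExperimentConfig", "run_experiment", "records_to_frame", "curve_table"]

_TRAIN_FRACTIONS = {"guangzhou_like": 0.8, "pakistan_like": 0.5}


@dataclass
class ExperimentConfig:
    dataset_preset: str = "pakistan_like"
    scale: float = 1.0
    train_fraction: float | None = None  # per-preset default when None
    dataset_kwargs: dict = field(default_factory=dict)
    encoders: list[dict] = field(
        default_factory=lambda: [
            {"kind": "oracle_informative", "informativeness": 0.9, "name": "domain_oracle"},
            {"kind": "generic_frozen", "name": "generic_frozen"},
        ]
    )
    encoder_pairs: list[list[str]] = field(
        default_factory=lambda: [["domain_oracle", "generic_frozen"]]
    )
    strategies: list[str] = field(default_factory=lambda: ["diversity", "uncertainty", "hybrid"])
    backbones: list[str] = field(default_factory=lambda: ["image", "embedding"])
    init_budgets: list[int] = field(default_factory=lambda: [10, 20, 30, 40, 50])
    initial_budget: int = 10
    per_iteration_budget: int = 10
    n_iterations: int = 4
    n_random_reps: int = 10
    n_al_reps: int = 2
    mc: MCDropoutConfig = field(default_factory=MCDropoutConfig)
    train: TrainingConfig = field(default_factory=TrainingConfig)
    estimator: TrainingConfig = field(default_factory=lambda: ESTIMATOR_CONFIG)
    n_boot: int = 200
    master_seed: int = 0
    output_dir: str = "results"

    @property
    def resolved_train_fraction(self) -> float:
        if self.train_fraction is not None:
            return self.train_fraction
        return _TRAIN_FRACTIONS.get(self.dataset_preset, 0.8)

    @property
    def schedule(self) -> BudgetSchedule:
        return BudgetSchedule(self.initial_budget, self.per_iteration_budget, self.n_iterations)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub_cls in (("mc", MCDropoutConfig), ("train", TrainingConfig), ("estimator", TrainingConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub_cls(**raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def records_to_frame(records: list[tuple[ALRunRecord, str, str, int]]) -> pd.DataFrame:
    """Tidy rows from (record, run_id, dataset, rep) tuples."""
    rows = []
    for record, run_id, dataset, rep in records:
        for cp in record.checkpoints:
            for metric, est in cp.metrics.items():
                rows.append(
                    {
                        "run_id": run_id,
                        "dataset": dataset,
                        "encoder": record.encoder_name,
                        "strategy": record.init_strategy,
                        "backbone": record.backbone,
                        "stage": cp.stage,
                        "budget": cp.budget,
                        "rep": rep,
                        "metric": metric,
                        "value": est.mean,
                        "sd": est.bootstrap_sd,
                        "minority_prop": cp.minority_proportion,
                    }
                )
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def curve_table(df: pd.DataFrame) -> pd.DataFrame:
    """Mean curve data per (dataset, encoder, strategy, backbone, stage, budget, metric)."""
    return (
        df.groupby(["dataset", "encoder", "strategy", "backbone", "stage", "budget", "metric"])
        .agg(mean=("value", "mean"), sd_between=("value", "std"), mean_boot_sd=("sd", "mean"),
             n=("value", "size"))
        .reset_index()
    )


def run_experiment(config: ExperimentConfig, progress: bool = False) -> dict:
    """Execute the whole grid; returns the tidy frame and writes artifacts."""
    out = Path(config.output_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    master = config.master_seed
    dataset_name = config.dataset_preset

    spec = preset(config.dataset_preset, config.scale,
                  seed=sub_seed(master, "dataset"), **config.dataset_kwargs)
    dataset = generate_dataset(spec)
    split = stratified_split(dataset, config.resolved_train_fraction, sub_seed(master, "split"))
    train_pool, test_set = split.train, split.test

    encoders = {}
    for enc_spec in config.encoders:
        enc_spec = dict(enc_spec)
        enc_spec.setdefault("seed", sub_seed(master, "encoder", enc_spec.get("name", enc_spec["kind"])))
        enc = make_encoder(**enc_spec)
        encoders[enc.name] = enc

    collected: list[tuple[ALRunRecord, str, str, int]] = []
    log: dict = {"runs": []}

    def note(msg: str) -> None:
        if progress:
            print(msg, flush=True)

    def add(record: ALRunRecord, run_id: str, rep: int) -> None:
        collected.append((record, run_id, dataset_name, rep))
        record.to_json(out / "runs" / f"{run_id}.json")
        log["runs"].append({"run_id": run_id, "seed": record.seed})

    representation_strategies = [s for s in config.strategies if s != "random"]

    for enc_name, enc in encoders.items():
        train_emb = encode(enc, train_pool)
        # one proxy estimator per encoder, shared across budgets and strategies
        scores = None
        if any(s in ("uncertainty", "hybrid") for s in representation_strategies):
            est_cfg = replace(config.estimator, seed=sub_seed(master, "estimator", enc_name))
            estimator, _ = train_uncertainty_estimator(train_pool.images, train_emb, est_cfg)
            scores = mc_dropout_variance(
                estimator, train_pool.images,
                replace(config.mc, seed=sub_seed(master, "mc", enc_name)),
                ids=train_emb.ids,
            )

        # initialization-only arms over the budget grid
        for strategy in representation_strategies:
            for budget in config.init_budgets:
                for backbone in config.backbones:
                    seed = sub_seed(master, "init", enc_name, strategy, budget, backbone)
                    record = run_al(
                        train_pool, test_set, enc, strategy, "uncertainty",
                        BudgetSchedule(budget), backbone=backbone,
                        train_config=config.train, estimator_config=config.estimator,
                        mc_config=config.mc, seed=seed, n_boot=config.n_boot,
                        init_scores=scores,
                    )
                    add(record, f"init_{enc_name}_{strategy}_b{budget}_{backbone}", 0)
                    note(f"done init {enc_name}/{strategy}/b{budget}/{backbone}")

        # full AL arms under the schedule
        for strategy in representation_strategies:
            for backbone in config.backbones:
                for rep in range(config.n_al_reps):
                    seed = sub_seed(master, "run", enc_name, strategy, backbone, rep)
                    record = run_al(
                        train_pool, test_set, enc, strategy, "uncertainty",
                        config.schedule, backbone=backbone,
                        train_config=config.train, estimator_config=config.estimator,
                        mc_config=config.mc, seed=seed, n_boot=config.n_boot,
                        init_scores=scores,
                    )
                    add(record, f"al_{enc_name}_{strategy}_{backbone}_r{rep}", rep)
                    note(f"done AL {enc_name}/{strategy}/{backbone}/rep{rep}")

    # nested random baselines (encoder-free, pixel backbone plus any others)
    reps = random_init(list(train_pool.ids), config.init_budgets,
                       n_reps=config.n_random_reps, seed=sub_seed(master, "random_init"))
    for backbone in config.backbones:
        enc_for_backbone = next(iter(encoders.values())) if backbone == "embedding" else None
        for rep, per_budget in enumerate(reps):
            for budget, query in per_budget.items():
                seed = sub_seed(master, "randinit", backbone, rep, budget)
                record = run_al(
                    train_pool, test_set, enc_for_backbone, query, "random",
                    BudgetSchedule(budget), backbone=backbone,
                    train_config=config.train, seed=seed, n_boot=config.n_boot,
                )
                add(record, f"randinit_{backbone}_r{rep}_b{budget}", rep)
        note(f"done random init arm ({backbone})")
        # random-throughout full AL baseline
        for rep in range(config.n_al_reps):
            seed = sub_seed(master, "randal", backbone, rep)
            record = run_al(
                train_pool, test_set, enc_for_backbone, "random", "random",
                config.schedule, backbone=backbone,
                train_config=config.train, seed=seed, n_boot=config.n_boot,
            )
            add(record, f"randal_{backbone}_r{rep}", rep)
        note(f"done random AL arm ({backbone})")

    # all-samples upper bound
    for backbone in config.backbones:
        enc_for_backbone = next(iter(encoders.values())) if backbone == "embedding" else None
        record = run_all_samples(
            train_pool, test_set, enc_for_backbone, backbone=backbone,
            train_config=config.train, seed=sub_seed(master, "all", backbone),
            n_boot=config.n_boot,
        )
        add(record, f"all_samples_{backbone}", 0)
        note(f"done all-samples ({backbone})")

    df = records_to_frame(collected)
    df.to_csv(out / "results.csv", index=False)
    curve_table(df).to_csv(out / "curves.csv", index=False)
    config.to_yaml(out / "config_resolved.yaml")
    (out / "log.json").write_text(json.dumps(log, indent=1))
    return {"results": df, "curves": curve_table(df), "output_dir": out}
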