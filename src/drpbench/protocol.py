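"""Orchestration of the full benchmark design.

A plan crosses evaluation regimes x split seeds x model seeds x methods,
computes every requested (metric, stratification) cell, and emits summary
tables in the benchmark's comparison format ("mean ± std" across model
seeds, "N/A" for undefined cells, best value per column flagged).  Split
files and prediction tables are cached on disk, so an interrupted run
resumes to identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import (
    MarkerBaselineConfig,
    fit_cl_average,
    fit_drug_average,
    fit_marker_baseline,
    predict_cl_average,
    predict_drug_average,
)
from .binarization import BinarizationMethod, BinarizationRule, binarize
from .data_model import (
    DrugSet,
    OmicsMatrix,
    PredictionScale,
    PredictionTable,
    ResponseTable,
    ValueKind,
)
from .metrics import (
    MetricReport,
    Stratification,
    metric_stratified,
    summarize_reports,
    write_report,
)
from .models import Ablation, ModelConfig, build_model, train, variant
from .splitting import Regime, load_split, make_split, save_split
from .synthetic import GeneratorConfig, generate_screen, inject_binarizable_structure

__all__ = ["ExperimentPlan", "ExperimentResult", "PlanError", "run_experiment",
           "build_comparison_table", "table_to_markdown"]

logger = logging.getLogger(__name__)

BASELINE_METHODS = ("drug_average", "cl_average", "marker")
MODEL_METHODS = ("two_branch", "minus_drug_branch", "all_marker")

# which regimes each method is defined for
VALID_REGIMES: dict[str, set[Regime]] = {
    "drug_average": {Regime.mixed_set, Regime.cancer_blind},
    "cl_average": {Regime.mixed_set, Regime.drug_blind},
    "marker": {Regime.mixed_set},
    "two_branch": {Regime.mixed_set, Regime.cancer_blind, Regime.drug_blind},
    "minus_drug_branch": {Regime.mixed_set, Regime.cancer_blind},
    "all_marker": {Regime.mixed_set},
}


class PlanError(ValueError):
    """An invalid (regime, method) combination or malformed plan."""


@dataclass(frozen=True)
class ExperimentPlan:
    generator: GeneratorConfig = GeneratorConfig()
    regimes: tuple[Regime, ...] = (Regime.mixed_set, Regime.cancer_blind, Regime.drug_blind)
    split_seeds: tuple[int, ...] = (0, 1, 2)
    model_seeds: tuple[int, ...] = (0, 1, 2)
    methods: tuple[str, ...] = ("drug_average", "cl_average", "two_branch")
    stratifications: tuple[Stratification, ...] = (
        Stratification.none,
        Stratification.by_cell_line,
        Stratification.by_drug,
    )
    binarize_targets: bool = False
    binarizable_noise: bool = False  # redraw noise to favour binary labels
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    model_config: ModelConfig = ModelConfig()
    marker_config: MarkerBaselineConfig = MarkerBaselineConfig()
    out_dir: str = "runs"

    def metric_names(self) -> tuple[str, ...]:
        return ("auc", "aupr", "bce") if self.binarize_targets else ("mse", "pearson", "r2")

    def validate(self) -> None:
        for method in self.methods:
            if method not in VALID_REGIMES:
                raise PlanError(f"unknown method {method!r}")
            for regime in self.regimes:
                if Regime(regime) not in VALID_REGIMES[method]:
                    raise PlanError(
                        f"method {method!r} is not defined for regime {Regime(regime).value!r}"
                    )


@dataclass
class ExperimentResult:
    plan: ExperimentPlan
    truth: ResponseTable
    reports: list[MetricReport]
    summary: pd.DataFrame
    out_dir: Path


def _method_regimes_ok(plan: ExperimentPlan) -> None:
    plan.validate()


def _fit_predict(
    method: str,
    plan: ExperimentPlan,
    split,
    truth: ResponseTable,
    omics: OmicsMatrix,
    drugs: DrugSet,
    model_seed: int,
) -> PredictionTable:
    train_tbl = truth.subset(split.train)
    val_tbl = truth.subset(split.validation) if split.validation else train_tbl
    test_keys = list(split.test)
    if method == "drug_average":
        return predict_drug_average(fit_drug_average(train_tbl), test_keys)
    if method == "cl_average":
        return predict_cl_average(fit_cl_average(train_tbl), test_keys)
    if method == "marker":
        cfg = replace(plan.marker_config, seed=model_seed)
        model = fit_marker_baseline(
            train_tbl, val_tbl, list(omics.cell_line_ids), list(drugs.drug_ids), cfg
        )
        return model.predict(test_keys)
    # two-branch family
    output = (
        PredictionScale.probability if plan.binarize_targets else PredictionScale.continuous
    )
    cfg = replace(plan.model_config, model_seed=model_seed, output=output)
    if method == "minus_drug_branch":
        cfg = variant(cfg, Ablation.minus_drug_branch)
    elif method == "all_marker":
        cfg = variant(cfg, Ablation.all_marker)
    model = build_model(cfg, omics, drugs)
    run = train(model, split, truth)
    return run.test_predictions


def run_experiment(plan: ExperimentPlan) -> ExperimentResult:
    """Execute every cell of the design; cached cells are skipped on re-runs."""
    _method_regimes_ok(plan)
    out_dir = Path(plan.out_dir)
    (out_dir / "splits").mkdir(parents=True, exist_ok=True)
    (out_dir / "predictions").mkdir(parents=True, exist_ok=True)

    table, omics, drugs, gt = generate_screen(plan.generator)
    if plan.binarizable_noise:
        table = inject_binarizable_structure(table, gt)
    if plan.binarize_targets:
        truth = binarize(table, BinarizationRule(BinarizationMethod.per_drug_mean))
    else:
        truth = table

    reports: list[MetricReport] = []
    scale = PredictionScale.probability if plan.binarize_targets else PredictionScale.continuous
    for regime in plan.regimes:
        regime = Regime(regime)
        for split_seed in plan.split_seeds:
            split_path = out_dir / "splits" / f"{regime.value}_seed{split_seed}.json"
            if split_path.exists():
                split = load_split(split_path)
            else:
                split = make_split(truth, regime, plan.fractions, split_seed)
                save_split(split, split_path)
            test_truth = truth.subset(split.test)
            for method in plan.methods:
                seeds = plan.model_seeds if method in MODEL_METHODS or method == "marker" else (plan.model_seeds[0],)
                for model_seed in seeds:
                    pred_path = (
                        out_dir
                        / "predictions"
                        / f"{regime.value}_s{split_seed}_{method}_k{model_seed}.csv"
                    )
                    if pred_path.exists():
                        df = pd.read_csv(
                            pred_path,
                            dtype={"cell_line": str, "drug": str},
                            float_precision="round_trip",
                        )
                        pred = PredictionTable(df, scale=scale)
                    else:
                        t0 = time.time()
                        pred = _fit_predict(method, plan, split, truth, omics, drugs, model_seed)
                        pred.records.to_csv(pred_path, index=False, float_format="%.17g")
                        logger.info(
                            "cell regime=%s split_seed=%d method=%s model_seed=%d wall=%.1fs",
                            regime.value, split_seed, method, model_seed, time.time() - t0,
                        )
                    for metric in plan.metric_names():
                        for strat in plan.stratifications:
                            reports.append(
                                metric_stratified(
                                    pred,
                                    test_truth,
                                    metric,
                                    strat,
                                    regime=regime.value,
                                    method=method,
                                    split_seed=split_seed,
                                    model_seed=model_seed,
                                )
                            )

    summary = summarize_reports(reports)
    summary = summary.sort_values(
        ["regime", "split_seed", "method", "stratification", "metric"]
    ).reset_index(drop=True)
    write_report(summary, out_dir / "metrics.csv")
    return ExperimentResult(plan=plan, truth=truth, reports=reports, summary=summary, out_dir=out_dir)


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------

_LOWER_IS_BETTER = {"mse", "bce"}

# column layouts of the benchmark's comparison-table styles
_STYLES: dict[str, dict] = {
    "table1": {  # stratified cancer-blind testing, continuous targets
        "regime": Regime.cancer_blind,
        "columns": [
            ("mse", Stratification.by_cell_line),
            ("pearson", Stratification.by_cell_line),
            ("r2", Stratification.by_cell_line),
            ("pearson", Stratification.by_drug),
            ("r2", Stratification.by_drug),
        ],
    },
    "table3": {  # drug-stratified testing, binary targets
        "regime": Regime.cancer_blind,
        "columns": [("auc", Stratification.by_drug), ("aupr", Stratification.by_drug)],
    },
    "table7": {  # mixed-set testing, binary targets, unstratified
        "regime": Regime.mixed_set,
        "columns": [("auc", Stratification.none), ("aupr", Stratification.none)],
    },
}


def _format_cell(mean, std) -> str:
    if mean is None or (isinstance(mean, float) and np.isnan(mean)):
        return "N/A"
    if std is None or (isinstance(std, float) and np.isnan(std)):
        return f"{mean:.3f}"
    return f"{mean:.3f} ± {std:.3f}"


def build_comparison_table(
    summary: pd.DataFrame, style: str, split_seed: int | None = None
) -> pd.DataFrame:
    """Rows = methods, columns = (metric, stratification), cells = "mean ± std".

    The best defined value per column is wrapped in ``**`` (bold in markdown);
    undefined cells print "N/A", missing cells are blank with a warning.
    """
    if style not in _STYLES:
        raise ValueError(f"unknown style {style!r}; choose from {sorted(_STYLES)}")
    layout = _STYLES[style]
    regime = layout["regime"].value
    sel = summary[summary["regime"] == regime]
    if split_seed is not None:
        sel = sel[sel["split_seed"] == split_seed]
    methods = list(dict.fromkeys(sel["method"]))
    col_names = [f"{m} ({s.value})" if s != Stratification.none else m for m, s in layout["columns"]]
    data: dict[str, list[str]] = {name: [] for name in col_names}
    raw: dict[str, list[float | None]] = {name: [] for name in col_names}
    for method in methods:
        for (metric, strat), name in zip(layout["columns"], col_names):
            rows = sel[
                (sel["method"] == method)
                & (sel["metric"] == metric)
                & (sel["stratification"] == strat.value)
            ]
            if len(rows) == 0:
                logger.warning("no result for method=%s column=%s", method, name)
                data[name].append("")
                raw[name].append(None)
                continue
            row = rows.iloc[0]
            mean = row["mean"] if pd.notna(row["mean"]) else None
            std = row["std"] if pd.notna(row["std"]) else None
            data[name].append(_format_cell(mean, std))
            raw[name].append(mean)
    # flag best value per column
    for (metric, _), name in zip(layout["columns"], col_names):
        values = raw[name]
        defined = [(i, v) for i, v in enumerate(values) if v is not None]
        if not defined:
            continue
        best_i = (min if metric in _LOWER_IS_BETTER else max)(defined, key=lambda iv: iv[1])[0]
        if data[name][best_i] not in ("", "N/A"):
            data[name][best_i] = f"**{data[name][best_i]}**"
    return pd.DataFrame(data, index=pd.Index(methods, name="method"))


def table_to_markdown(table: pd.DataFrame) -> str:
    header = "| method | " + " | ".join(table.columns) + " |"
    rule = "|" + "---|" * (len(table.columns) + 1)
    lines = [header, rule]
    for method, row in table.iterrows():
        lines.append("| " + " | ".join([str(method)] + [str(v) for v in row]) + " |")
    return "\n".join(lines)
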