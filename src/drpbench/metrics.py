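"""Evaluation metrics under the three stratification schemes.

A metric can be computed once over all test (cell line, drug) pairs
(unstratified), or within each test cell line / each test drug and then
averaged (stratified).  Stratified averaging is *unweighted* over strata, and
strata where a metric is undefined (constant vectors for Pearson, a single
class for AUC/AUPR, fewer than two pairs for correlation metrics) are
excluded from the average and counted explicitly.  A report whose strata are
all undefined aggregates to "N/A", never to 0 — the distinction matters:
a constant-per-drug predictor has an *undefined* drug-stratified Pearson,
not a zero one.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_model import (
    FormatError,
    PredictionTable,
    ResponseTable,
    ValueKind,
)

__all__ = [
    "Stratification",
    "MetricReport",
    "CONTINUOUS_METRICS",
    "BINARY_METRICS",
    "metric_unstratified",
    "metric_stratified",
    "aggregate_over_seeds",
    "summarize_reports",
    "write_report",
    "read_report",
]

CONTINUOUS_METRICS = ("mse", "pearson", "r2")
BINARY_METRICS = ("auc", "aupr", "bce")

_EPS = 1e-12


class Stratification(str, enum.Enum):
    by_cell_line = "by_cell_line"
    by_drug = "by_drug"
    none = "none"


@dataclass(frozen=True)
class MetricReport:
    """Per-stratum and aggregated values for one (metric, stratification).

    ``aggregate`` is the unweighted mean over the ``n_strata - n_undefined``
    defined strata, or None when every stratum is undefined.
    """

    metric: str
    stratification: Stratification
    per_stratum: Mapping[str, float | None]
    aggregate: float | None
    n_strata: int
    n_undefined: int
    regime: str | None = None
    method: str | None = None
    split_seed: int | None = None
    model_seed: int | None = None

    def __post_init__(self) -> None:
        defined = [v for v in self.per_stratum.values() if v is not None]
        if len(defined) != self.n_strata - self.n_undefined:
            raise ValueError("n_undefined inconsistent with per-stratum values")
        if self.n_undefined == self.n_strata and self.aggregate is not None:
            raise ValueError("fully-undefined report must aggregate to None (N/A)")


# ---------------------------------------------------------------------------
# metric primitives: return None when the metric is undefined
# ---------------------------------------------------------------------------

def _mse(y: np.ndarray, p: np.ndarray) -> float:
    return float(np.mean((y - p) ** 2))


def _pearson(y: np.ndarray, p: np.ndarray) -> float | None:
    if len(y) < 2 or np.ptp(y) == 0 or np.ptp(p) == 0:
        return None
    return float(stats.pearsonr(y, p).statistic)


def _r2(y: np.ndarray, p: np.ndarray) -> float | None:
    # coefficient of determination against the stratum's own truth mean;
    # may be negative for predictors worse than that mean
    if len(y) < 2:
        return None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return None
    ss_res = float(np.sum((y - p) ** 2))
    return 1.0 - ss_res / ss_tot


def _auc(y: np.ndarray, p: np.ndarray) -> float | None:
    # tie-aware Mann-Whitney convention: ties contribute 1/2, so a constant
    # scorer has AUC exactly 0.5 whenever both classes are present
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, p))


def _aupr(y: np.ndarray, p: np.ndarray) -> float | None:
    # step-wise precision-recall integration, no interpolation
    if len(np.unique(y)) < 2:
        return None
    return float(average_precision_score(y, p))


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    q = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(q) + (1.0 - y) * np.log(1.0 - q)))


_METRIC_FN = {"mse": _mse, "pearson": _pearson, "r2": _r2, "auc": _auc, "aupr": _aupr, "bce": _bce}


def _check_compat(metric: str, truth: ResponseTable) -> None:
    if metric not in _METRIC_FN:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_FN)}")
    if metric in BINARY_METRICS and truth.value_kind != ValueKind.binary:
        raise FormatError(f"metric {metric!r} requires binary truth values")
    if metric in CONTINUOUS_METRICS and truth.value_kind == ValueKind.binary:
        raise FormatError(f"metric {metric!r} requires continuous truth values")


def _aligned_arrays(pred: PredictionTable, truth: ResponseTable) -> pd.DataFrame:
    pmap = pred.prediction_map()
    tkeys = truth.keys
    if set(pmap) != set(tkeys):
        missing = set(tkeys) - set(pmap)
        extra = set(pmap) - set(tkeys)
        raise FormatError(
            f"prediction/truth key mismatch: {len(missing)} truth keys unpredicted, "
            f"{len(extra)} predictions without truth"
        )
    df = truth.records.copy()
    df["prediction"] = [pmap[k] for k in tkeys]
    return df


def metric_unstratified(pred: PredictionTable, truth: ResponseTable, metric: str) -> float | None:
    """One metric value over all test pairs; None if undefined on the whole set."""
    _check_compat(metric, truth)
    df = _aligned_arrays(pred, truth)
    return _METRIC_FN[metric](df["value"].to_numpy(), df["prediction"].to_numpy())


def metric_stratified(
    pred: PredictionTable,
    truth: ResponseTable,
    metric: str,
    by: Stratification | str,
    **report_labels,
) -> MetricReport:
    """Compute `metric` within each test cell line or drug, then average.

    ``by=Stratification.none`` yields a single stratum ("all") so that the
    stratified and unstratified paths coincide by construction.
    """
    by = Stratification(by)
    _check_compat(metric, truth)
    df = _aligned_arrays(pred, truth)
    if by == Stratification.none:
        groups: Iterable[tuple[str, pd.DataFrame]] = [("all", df)]
    else:
        col = "cell_line" if by == Stratification.by_cell_line else "drug"
        groups = sorted(df.groupby(col, sort=True), key=lambda kv: kv[0])
    per_stratum: dict[str, float | None] = {}
    for name, g in groups:
        per_stratum[str(name)] = _METRIC_FN[metric](
            g["value"].to_numpy(), g["prediction"].to_numpy()
        )
    defined = [v for v in per_stratum.values() if v is not None]
    return MetricReport(
        metric=metric,
        stratification=by,
        per_stratum=per_stratum,
        aggregate=float(np.mean(defined)) if defined else None,
        n_strata=len(per_stratum),
        n_undefined=len(per_stratum) - len(defined),
        **report_labels,
    )


# ---------------------------------------------------------------------------
# aggregation across model seeds, and report I/O
# ---------------------------------------------------------------------------

def aggregate_over_seeds(reports: Sequence[MetricReport]) -> dict:
    """Mean and sample std of the aggregate value across model seeds.

    All reports must share metric, stratification and regime. Undefined
    aggregates stay undefined: if every seed's aggregate is None the summary
    mean is None.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    head = reports[0]
    for r in reports[1:]:
        if (r.metric, r.stratification, r.regime, r.method) != (
            head.metric,
            head.stratification,
            head.regime,
            head.method,
        ):
            raise ValueError("reports mix metrics, stratifications, regimes or methods")
    values = [r.aggregate for r in reports if r.aggregate is not None]
    n_undefined = int(np.mean([r.n_undefined for r in reports])) if reports else 0
    split_seeds = {r.split_seed for r in reports}
    return {
        "method": head.method,
        "regime": head.regime,
        "stratification": head.stratification.value,
        "metric": head.metric,
        "split_seed": head.split_seed if len(split_seeds) == 1 else None,
        "mean": float(np.mean(values)) if values else None,
        "std": float(np.std(values, ddof=1)) if len(values) >= 2 else None,
        "n_seeds": len(reports),
        "n_undefined": n_undefined,
    }


_REPORT_COLUMNS = [
    "method",
    "regime",
    "stratification",
    "metric",
    "split_seed",
    "mean",
    "std",
    "n_seeds",
    "n_undefined",
]


def summarize_reports(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Group seed-level reports and aggregate each group into one summary row."""
    groups: dict[tuple, list[MetricReport]] = {}
    for r in reports:
        key = (r.method, r.regime, r.stratification, r.metric, r.split_seed)
        groups.setdefault(key, []).append(r)
    rows = [aggregate_over_seeds(v) for v in groups.values()]
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_report(summary: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write one row per (method, regime, stratification, metric); undefined
    aggregates print as "N/A". Round-trips through :func:`read_report`."""
    df = summary.copy()
    missing = [c for c in _REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"report missing columns: {missing}")
    for col in ("mean", "std"):
        df[col] = df[col].map(lambda v: "N/A" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v)))
    df.to_csv(path, sep=delimiter, index=False)


def read_report(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=delimiter, dtype={"method": str, "regime": str},
        float_precision="round_trip",
    )
    for col in ("mean", "std"):
        df[col] = pd.Series(
            [
                None
                if v is None or str(v) == "N/A" or (isinstance(v, float) and math.isnan(v))
                else float(v)
                for v in df[col]
            ],
            dtype=object,
            index=df.index,
        )
    return df
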