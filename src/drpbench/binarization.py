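"""Binarize continuous ln(IC50) responses into sensitive/resistant labels.

Label convention: value strictly below the threshold means the drug killed
the cell line at a lower concentration than the reference point, i.e. the
pair is *sensitive* (label 1); at or above the threshold it is resistant
(label 0).  Thresholds are computed once on the full table, before any
train/test split — the binary truth value is a property of the experiment,
not of a fold.  Set ``positive_is_sensitive=False`` to complement every
label.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import FormatError, ResponseTable, ValueKind

__all__ = ["BinarizationMethod", "BinarizationRule", "binarize", "class_balance"]


class BinarizationMethod(str, enum.Enum):
    global_threshold = "global_threshold"
    per_drug_mean = "per_drug_mean"
    per_drug_threshold_table = "per_drug_threshold_table"


@dataclass(frozen=True)
class BinarizationRule:
    method: BinarizationMethod = BinarizationMethod.global_threshold
    threshold: float | Mapping[str, float] | None = None
    positive_is_sensitive: bool = True

    def __post_init__(self) -> None:
        method = BinarizationMethod(self.method)
        object.__setattr__(self, "method", method)
        if method == BinarizationMethod.global_threshold and not isinstance(
            self.threshold, (int, float)
        ):
            raise ValueError("global_threshold requires a scalar threshold")
        if method == BinarizationMethod.per_drug_threshold_table and not isinstance(
            self.threshold, Mapping
        ):
            raise ValueError("per_drug_threshold_table requires a drug -> threshold mapping")


def _per_drug_thresholds(table: ResponseTable, rule: BinarizationRule) -> dict[str, float]:
    df = table.records
    if rule.method == BinarizationMethod.per_drug_threshold_table:
        thresholds = dict(rule.threshold)
        missing = sorted(set(df["drug"]) - set(thresholds))
        if missing:
            raise FormatError(f"threshold table missing drugs: {missing[:5]}")
        return thresholds
    if rule.method == BinarizationMethod.global_threshold:
        return {d: float(rule.threshold) for d in df["drug"].unique()}
    # per_drug_mean: a drug with a single record has no informative mean —
    # fall back to the global mean of the full table, with a warning
    global_mean = float(df["value"].mean())
    thresholds = {}
    for drug, g in df.groupby("drug"):
        if len(g) < 2:
            warnings.warn(
                f"drug {drug!r} has a single record; using the global mean "
                f"{global_mean:.4g} as its binarization threshold",
                stacklevel=3,
            )
            thresholds[str(drug)] = global_mean
        else:
            values = g["value"].to_numpy()
            if np.ptp(values) == 0:
                warnings.warn(
                    f"drug {drug!r} has all-equal response values; every label "
                    "will be 0 under the strict-less convention",
                    stacklevel=3,
                )
            thresholds[str(drug)] = float(values.mean())
    return thresholds


def binarize(table: ResponseTable, rule: BinarizationRule) -> ResponseTable:
    """Map each record's value to 1 if strictly below its drug's threshold, else 0."""
    if table.value_kind == ValueKind.binary:
        raise FormatError("table is already binary; binarize expects continuous values")
    thresholds = _per_drug_thresholds(table, rule)
    df = table.records
    thr = df["drug"].map(thresholds).to_numpy(dtype=float)
    labels = (df["value"].to_numpy() < thr).astype(float)
    if not rule.positive_is_sensitive:
        labels = 1.0 - labels
    out = pd.DataFrame({"cell_line": df["cell_line"], "drug": df["drug"], "value": labels})
    return ResponseTable(out, value_kind=ValueKind.binary)


def class_balance(table: ResponseTable) -> tuple[float, dict[str, float]]:
    """Overall and per-drug positive fraction of a binary table."""
    if table.value_kind != ValueKind.binary:
        raise FormatError("class_balance requires a binary table")
    if len(table) == 0:
        raise ValueError("empty table")
    df = table.records
    overall = float(df["value"].mean())
    per_drug = {str(d): float(g["value"].mean()) for d, g in df.groupby("drug")}
    return overall, per_drug
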