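"""Null-hypothesis baselines that use no omics or chemical information.

* Drug average — predicts, for every test pair of drug *d*, the plain mean of
  *d*'s training responses (intended for cancer-blind and mixed-set testing,
  where all test drugs were seen in training).
* Cell-line (CL) average — the mirror image over cell lines (drug-blind and
  mixed-set).
* Marker baseline — an MLP over concatenated one-hot ("marker") cell and drug
  vectors: pure identity in, response out.  Intended for mixed-set testing,
  where every test entity occurred in training, so everything it can learn
  comes from the distribution of training truth values.

What these baselines achieve is the yardstick for how much performance omics
profiles and drug structures actually add.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .data_model import (
    PredictionScale,
    PredictionTable,
    ResponseTable,
    ValueKind,
)

__all__ = [
    "DrugAverageModel",
    "CLAverageModel",
    "MarkerBaselineConfig",
    "MarkerBaselineModel",
    "fit_drug_average",
    "predict_drug_average",
    "fit_cl_average",
    "predict_cl_average",
    "fit_marker_baseline",
    "predict_marker_baseline",
]

Key = tuple[str, str]


@dataclass(frozen=True)
class DrugAverageModel:
    per_drug_mean: dict[str, float]
    per_drug_count: dict[str, int]  # n_d over training cell lines; varies with missingness
    value_kind: ValueKind = ValueKind.continuous_lnIC50


@dataclass(frozen=True)
class CLAverageModel:
    per_cell_mean: dict[str, float]
    per_cell_count: dict[str, int]
    value_kind: ValueKind = ValueKind.continuous_lnIC50


def fit_drug_average(train: ResponseTable) -> DrugAverageModel:
    grouped = train.records.groupby("drug")["value"]
    return DrugAverageModel(
        per_drug_mean={str(d): float(m) for d, m in grouped.mean().items()},
        per_drug_count={str(d): int(n) for d, n in grouped.count().items()},
        value_kind=train.value_kind,
    )


def predict_drug_average(model: DrugAverageModel, test_keys: Sequence[Key]) -> PredictionTable:
    """Constant per drug across all test cell lines."""
    unseen = sorted({d for _, d in test_keys} - set(model.per_drug_mean))
    if unseen:
        raise KeyError(
            f"drugs {unseen[:5]} have no training records; the drug-average "
            "baseline is undefined for unseen drugs (use it for cancer-blind or "
            "mixed-set testing, not drug-blind)"
        )
    scale = (
        PredictionScale.probability
        if model.value_kind == ValueKind.binary
        else PredictionScale.continuous
    )
    return PredictionTable.from_records(
        [(c, d, model.per_drug_mean[d]) for c, d in test_keys], scale=scale
    )


def fit_cl_average(train: ResponseTable) -> CLAverageModel:
    grouped = train.records.groupby("cell_line")["value"]
    return CLAverageModel(
        per_cell_mean={str(c): float(m) for c, m in grouped.mean().items()},
        per_cell_count={str(c): int(n) for c, n in grouped.count().items()},
        value_kind=train.value_kind,
    )


def predict_cl_average(model: CLAverageModel, test_keys: Sequence[Key]) -> PredictionTable:
    unseen = sorted({c for c, _ in test_keys} - set(model.per_cell_mean))
    if unseen:
        raise KeyError(
            f"cell lines {unseen[:5]} have no training records; the CL-average "
            "baseline is undefined for unseen cell lines (use it for drug-blind "
            "or mixed-set testing, not cancer-blind)"
        )
    scale = (
        PredictionScale.probability
        if model.value_kind == ValueKind.binary
        else PredictionScale.continuous
    )
    return PredictionTable.from_records(
        [(c, d, model.per_cell_mean[c]) for c, d in test_keys], scale=scale
    )


# ---------------------------------------------------------------------------
# marker baseline: one-hot identity MLP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerBaselineConfig:
    hidden: tuple[int, ...] = (256, 256)
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0


class MarkerBaselineModel:
    """MLP over [one-hot cell | one-hot drug]; the loss matches the target kind
    (MSE for continuous responses, BCE for binary) so it is a fair null."""

    def __init__(
        self,
        cell_ids: Sequence[str],
        drug_ids: Sequence[str],
        config: MarkerBaselineConfig,
        value_kind: ValueKind,
    ):
        self.cell_index = {c: i for i, c in enumerate(cell_ids)}
        self.drug_index = {d: i for i, d in enumerate(drug_ids)}
        self.config = config
        self.value_kind = ValueKind(value_kind)
        rng = np.random.default_rng(config.seed)
        dims = [len(cell_ids) + len(drug_ids), *config.hidden, 1]
        self.net = nn.MLP(dims, rng)
        self.train_losses: list[float] = []
        self.val_losses: list[float] = []
        self.selected_epoch: int | None = None

    # input assembly -----------------------------------------------------
    def _encode(self, keys: Sequence[Key]) -> np.ndarray:
        n_cells, n_drugs = len(self.cell_index), len(self.drug_index)
        X = np.zeros((len(keys), n_cells + n_drugs))
        for row, (c, d) in enumerate(keys):
            if c not in self.cell_index:
                raise KeyError(f"cell line {c!r} not among the marker ids")
            if d not in self.drug_index:
                raise KeyError(f"drug {d!r} not among the marker ids")
            X[row, self.cell_index[c]] = 1.0
            X[row, n_cells + self.drug_index[d]] = 1.0
        return X

    def _loss(self, logits: nn.Tensor, y: np.ndarray) -> nn.Tensor:
        if self.value_kind == ValueKind.binary:
            return nn.bce_with_logits_loss(logits, y)
        return nn.mse_loss(logits, y)

    def _eval_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        self.net.set_training(False)
        out = self.net(nn.Tensor(X)).reshape(-1)
        return float(self._loss(out, y).data)

    def fit(self, train: ResponseTable, validation: ResponseTable) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        Xtr = self._encode(train.keys)
        ytr = train.records["value"].to_numpy()
        Xva = self._encode(validation.keys)
        yva = validation.records["value"].to_numpy()
        opt = nn.Adam(self.net.parameters(), lr=cfg.learning_rate)
        best_val, best_state, best_epoch = np.inf, self.net.state(), -1
        since_best = 0
        for epoch in range(cfg.max_epochs):
            self.net.set_training(True)
            for batch in _batches(len(Xtr), cfg.batch_size, rng):
                out = self.net(nn.Tensor(Xtr[batch])).reshape(-1)
                loss = self._loss(out, ytr[batch])
                self.net.zero_grad()
                loss.backward()
                opt.step()
            self.train_losses.append(self._eval_loss(Xtr, ytr))
            val = self._eval_loss(Xva, yva)
            self.val_losses.append(val)
            if val < best_val - 1e-9:
                best_val, best_state, best_epoch = val, self.net.state(), epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        self.net.load_state(best_state)
        self.selected_epoch = best_epoch

    def predict(self, keys: Sequence[Key]) -> PredictionTable:
        self.net.set_training(False)
        X = self._encode(keys)
        out = self.net(nn.Tensor(X)).reshape(-1).data
        if self.value_kind == ValueKind.binary:
            probs = 1.0 / (1.0 + np.exp(-out))
            return PredictionTable.from_records(
                [(c, d, float(p)) for (c, d), p in zip(keys, probs)],
                scale=PredictionScale.probability,
            )
        return PredictionTable.from_records(
            [(c, d, float(p)) for (c, d), p in zip(keys, out)],
            scale=PredictionScale.continuous,
        )


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def fit_marker_baseline(
    train: ResponseTable,
    validation: ResponseTable,
    cell_ids: Sequence[str],
    drug_ids: Sequence[str],
    config: MarkerBaselineConfig = MarkerBaselineConfig(),
) -> MarkerBaselineModel:
    """Train the one-hot MLP; epoch selection on validation loss."""
    model = MarkerBaselineModel(cell_ids, drug_ids, config, train.value_kind)
    # fail fast if any train/val entity is missing from the marker inventory
    model._encode(train.keys)
    model._encode(validation.keys)
    model.fit(train, validation)
    return model


def predict_marker_baseline(model: MarkerBaselineModel, keys: Sequence[Key]) -> PredictionTable:
    return model.predict(keys)
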