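"""The two-branch reference model and its ablations.

The reference architecture mirrors the dominant DRP design: a cell-line
branch (three-layer MLP over the omics profile), a drug branch (a stack of
transformer encoder layers over the tokenized SMILES string, mean-pooled
over non-pad positions), and a three-layer fusion MLP over the concatenated
branch outputs that emits either a continuous ln(IC50) prediction or a
sensitivity probability (sigmoid on the logit).

Two ablations isolate where performance comes from:

* ``minus_drug_branch`` ("-DB") — the transformer is replaced by a raw
  one-hot marker of drug identity, severing any path from chemical structure
  to the output while keeping drug identity available.
* ``all_marker`` — additionally replaces the omics input with a one-hot cell
  marker, leaving the network nothing but identities to learn from (the
  marker-baseline family with this architecture).

Training follows the benchmark protocol: mini-batch Adam on the split's
training pairs, epoch selection by validation loss, fully reproducible from
``(split_seed, model_seed)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from .data_model import (
    DrugSet,
    OmicsMatrix,
    PredictionScale,
    PredictionTable,
    ResponseTable,
    ValueKind,
)
from .splitting import SplitAssignment
from .tokenizer import SmilesVocabulary, TokenizedDrug, tokenize_smiles

__all__ = [
    "DrugBranchKind",
    "CellInputKind",
    "Ablation",
    "ModelConfig",
    "TwoBranchModel",
    "TrainingRun",
    "build_model",
    "variant",
    "train",
    "predict",
]

Key = tuple[str, str]


class DrugBranchKind(str, enum.Enum):
    transformer_encoder_stack = "transformer_encoder_stack"
    marker_passthrough = "marker_passthrough"
    absent = "absent"


class CellInputKind(str, enum.Enum):
    omics = "omics"
    marker = "marker"


class Ablation(str, enum.Enum):
    minus_drug_branch = "minus_drug_branch"
    all_marker = "all_marker"


@dataclass(frozen=True)
class ModelConfig:
    # cell branch: three-layer MLP features -> hidden -> hidden -> embedding
    cell_hidden: tuple[int, int] = (128, 64)
    cell_embed_dim: int = 32
    # drug branch (transformer encoder stack)
    d_model: int = 64
    n_encoder_layers: int = 2
    n_heads: int = 4
    ff_dim: int = 128
    max_smiles_len: int = 128
    dropout: float = 0.0
    # fusion: three-layer MLP to a single output
    fusion_hidden: tuple[int, int] = (64, 32)
    output: PredictionScale = PredictionScale.continuous
    drug_branch: DrugBranchKind = DrugBranchKind.transformer_encoder_stack
    cell_input: CellInputKind = CellInputKind.omics
    # optimisation
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    model_seed: int = 0


@dataclass
class TrainingRun:
    split_seed: int
    model_seed: int
    train_losses: list[float]
    val_losses: list[float]
    selected_epoch: int
    test_predictions: PredictionTable


class TwoBranchModel(nn.Module):
    """Cell branch + drug branch + fusion head, assembled against one screen's
    omics matrix and drug set."""

    def __init__(self, config: ModelConfig, omics: OmicsMatrix, drugs: DrugSet):
        self.config = config
        self.omics = omics
        self.drugs = drugs
        rng = np.random.default_rng(config.model_seed)

        self.cell_index = {c: i for i, c in enumerate(omics.cell_line_ids)}
        self.drug_index = {d: i for i, d in enumerate(drugs.drug_ids)}

        if config.cell_input == CellInputKind.omics:
            cell_in = len(omics.feature_ids)
        else:  # marker: identity one-hot per cell line, no omics path at all
            cell_in = len(omics.cell_line_ids)
        self.cell_branch = nn.MLP(
            [cell_in, *config.cell_hidden, config.cell_embed_dim], rng
        )

        self.vocabulary: SmilesVocabulary | None = None
        self.drug_encoder: nn.TransformerEncoder | None = None
        self._token_cache: dict[str, TokenizedDrug] = {}
        if config.drug_branch == DrugBranchKind.transformer_encoder_stack:
            self.vocabulary = SmilesVocabulary.build(
                [drugs.smiles_for(d) for d in drugs.drug_ids]
            )
            self.drug_encoder = nn.TransformerEncoder(
                vocab_size=len(self.vocabulary),
                d_model=config.d_model,
                n_layers=config.n_encoder_layers,
                n_heads=config.n_heads,
                ff_dim=config.ff_dim,
                max_len=config.max_smiles_len,
                rng=rng,
                pad_id=self.vocabulary.pad_id,
                dropout=config.dropout,
            )
            drug_dim = config.d_model
        elif config.drug_branch == DrugBranchKind.marker_passthrough:
            drug_dim = len(drugs.drug_ids)
        else:
            drug_dim = 0

        self.drug_dim = drug_dim
        self.fusion = nn.MLP(
            [config.cell_embed_dim + drug_dim, *config.fusion_hidden, 1], rng
        )

    # -- input assembly --------------------------------------------------
    def _cell_inputs(self, cell_ids: Sequence[str]) -> np.ndarray:
        missing = [c for c in cell_ids if c not in self.cell_index]
        if missing:
            raise KeyError(f"cell lines without an omics row: {sorted(set(missing))[:5]}")
        if self.config.cell_input == CellInputKind.omics:
            return self.omics.rows(list(cell_ids))
        X = np.zeros((len(cell_ids), len(self.cell_index)))
        for row, c in enumerate(cell_ids):
            X[row, self.cell_index[c]] = 1.0
        return X

    def _tokens_for(self, drug_id: str) -> TokenizedDrug:
        if drug_id not in self._token_cache:
            smiles = self.drugs.smiles_for(drug_id)
            self._token_cache[drug_id] = tokenize_smiles(
                smiles, self.vocabulary, self.config.max_smiles_len
            )
        return self._token_cache[drug_id]

    def _drug_embedding(self, drug_ids: Sequence[str]) -> nn.Tensor | None:
        missing = [d for d in drug_ids if d not in self.drug_index]
        if missing:
            raise KeyError(f"drugs not in the drug set: {sorted(set(missing))[:5]}")
        cfg = self.config
        if cfg.drug_branch == DrugBranchKind.absent:
            return None
        if cfg.drug_branch == DrugBranchKind.marker_passthrough:
            X = np.zeros((len(drug_ids), len(self.drug_index)))
            for row, d in enumerate(drug_ids):
                X[row, self.drug_index[d]] = 1.0
            return nn.Tensor(X)
        # encode each unique drug once, then gather back to the batch rows
        unique = list(dict.fromkeys(drug_ids))
        toks = [self._tokens_for(d) for d in unique]
        L = max(t.length for t in toks)
        mat = np.stack([t.token_ids[:L] for t in toks])
        encoded = self.drug_encoder(mat)  # (n_unique, d_model)
        pos = {d: i for i, d in enumerate(unique)}
        return encoded.take_rows(np.array([pos[d] for d in drug_ids]))

    def forward(self, keys: Sequence[Key]) -> nn.Tensor:
        """Logits (continuous prediction or pre-sigmoid score), shape (n,)."""
        cells = [c for c, _ in keys]
        drs = [d for _, d in keys]
        cell_out = self.cell_branch(nn.Tensor(self._cell_inputs(cells)))
        drug_out = self._drug_embedding(drs)
        fused = cell_out if drug_out is None else nn.concat([cell_out, drug_out], axis=-1)
        return self.fusion(fused).reshape(-1)

    def predict_values(self, keys: Sequence[Key]) -> np.ndarray:
        self.set_training(False)
        out = self.forward(keys).data
        if self.config.output == PredictionScale.probability:
            out = 1.0 / (1.0 + np.exp(-out))
        return out


def build_model(config: ModelConfig, omics: OmicsMatrix, drugs: DrugSet) -> TwoBranchModel:
    return TwoBranchModel(config, omics, drugs)


def variant(base_config: ModelConfig, ablation: Ablation | str) -> ModelConfig:
    """Derive an ablated configuration from a base one."""
    ablation = Ablation(ablation)
    if ablation == Ablation.minus_drug_branch:
        return replace(base_config, drug_branch=DrugBranchKind.marker_passthrough)
    return replace(
        base_config,
        drug_branch=DrugBranchKind.marker_passthrough,
        cell_input=CellInputKind.marker,
    )


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(
    model: TwoBranchModel,
    split: SplitAssignment,
    table: ResponseTable,
    run_test_predictions: bool = True,
) -> TrainingRun:
    """Fit on the split's training pairs with validation-based epoch selection."""
    cfg = model.config
    if cfg.output == PredictionScale.probability and table.value_kind != ValueKind.binary:
        raise ValueError("probability output requires binary truth values")
    if cfg.output == PredictionScale.continuous and table.value_kind == ValueKind.binary:
        raise ValueError("continuous output requires continuous truth values")

    vmap = table.value_map()
    train_keys = list(split.train)
    val_keys = list(split.validation)
    ytr = np.array([vmap[k] for k in train_keys])
    yva = np.array([vmap[k] for k in val_keys])

    def loss_fn(logits: nn.Tensor, y: np.ndarray) -> nn.Tensor:
        if cfg.output == PredictionScale.probability:
            return nn.bce_with_logits_loss(logits, y)
        return nn.mse_loss(logits, y)

    def eval_loss(keys: list[Key], y: np.ndarray) -> float:
        model.set_training(False)
        total, n = 0.0, 0
        for start in range(0, len(keys), cfg.batch_size):
            chunk = keys[start : start + cfg.batch_size]
            out = model.forward(chunk)
            total += float(loss_fn(out, y[start : start + cfg.batch_size]).data) * len(chunk)
            n += len(chunk)
        return total / n

    rng = np.random.default_rng(cfg.model_seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val, best_state, best_epoch = np.inf, model.state(), -1
    since_best = 0
    for epoch in range(cfg.max_epochs):
        model.set_training(True)
        for batch in _batches(len(train_keys), cfg.batch_size, rng):
            keys = [train_keys[i] for i in batch]
            out = model.forward(keys)
            loss = loss_fn(out, ytr[batch])
            model.zero_grad()
            loss.backward()
            opt.step()
        train_losses.append(eval_loss(train_keys, ytr))
        val = eval_loss(val_keys, yva) if val_keys else train_losses[-1]
        val_losses.append(val)
        if val < best_val - 1e-9:
            best_val, best_state, best_epoch = val, model.state(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state(best_state)

    if run_test_predictions:
        preds = predict(model, list(split.test))
    else:
        preds = PredictionTable.from_records(
            [(c, d, 0.0) for c, d in split.test[:1]], scale=PredictionScale.continuous
        )
    return TrainingRun(
        split_seed=split.split_seed,
        model_seed=cfg.model_seed,
        train_losses=train_losses,
        val_losses=val_losses,
        selected_epoch=best_epoch,
        test_predictions=preds,
    )


def predict(
    model: TwoBranchModel,
    keys: Sequence[Key],
    omics: OmicsMatrix | None = None,
    drugs: DrugSet | None = None,
) -> PredictionTable:
    """One prediction per key, deterministic in evaluation mode.

    `omics`/`drugs` override the containers the model was built against (the
    architecture must match: same features, same drug inventory)."""
    if omics is not None:
        if tuple(omics.feature_ids) != tuple(model.omics.feature_ids):
            raise ValueError("replacement omics matrix has different features")
        model.omics = omics
        model.cell_index = {c: i for i, c in enumerate(omics.cell_line_ids)}
    if drugs is not None:
        if tuple(drugs.drug_ids) != tuple(model.drugs.drug_ids):
            raise ValueError("replacement drug set has different drugs")
        model.drugs = drugs
        model._token_cache.clear()
    values = model.predict_values(list(keys))
    return PredictionTable.from_records(
        [(c, d, float(v)) for (c, d), v in zip(keys, values)],
        scale=model.config.output,
    )
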