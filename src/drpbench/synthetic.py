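"""Synthetic drug screens with a controlled variance decomposition.

The generator emulates the statistical structure of a large ln(IC50) screen:

    y_ij = grand_mean + a_j + b_i + g(x_i, s_j) + eps_ij

* ``a_j ~ N(0, sd_drug_effect^2)`` — a drug main effect: some drugs kill most
  cell lines, others kill few.  In real screens this component explains much
  of the between-drug variance and is exactly what the drug-average null
  baseline captures.
* ``b_i ~ N(0, sd_cell_effect^2)`` — a cell-line main effect: some lines are
  generally easier to kill.
* ``g(x_i, s_j) = x_i[signal]^T W s_j`` — an optional bilinear interaction
  carried by a small set of omics features and a latent per-drug descriptor,
  with ``W`` scaled so Var(g) ~ sd_interaction^2.  It is invisible to
  main-effect baselines but learnable by a two-branch model.
* ``eps_ij ~ N(0, sd_noise^2)`` — experimental noise.

Pairs are dropped independently with probability ``missing_fraction``
(missingness is absence of the triplet).  Omics features outside the signal
set are independent N(0,1) noise.  With ``smiles_informative=True`` the drug
SMILES atom composition encodes the leading descriptor components, so the
drug branch of a model can in principle recover chemistry-borne signal;
otherwise SMILES are random decoys.  Everything is reproducible from
``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    DrugSet,
    OmicsKind,
    OmicsMatrix,
    PredictionTable,
    ResponseTable,
    ValueKind,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_screen", "generate_smiles",
           "inject_binarizable_structure"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_cell_lines: int = 100
    n_drugs: int = 30
    n_features: int = 50
    missing_fraction: float = 0.15
    sd_drug_effect: float = 2.0
    sd_cell_effect: float = 0.8
    sd_interaction: float = 0.5
    sd_noise: float = 0.7
    grand_mean: float = 2.5
    n_signal_features: int = 5
    latent_dim: int = 4
    smiles_informative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_drug_effect, self.sd_cell_effect, self.sd_interaction, self.sd_noise) < 0:
            raise ValueError("variance components must be non-negative")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.n_signal_features > self.n_features:
            raise ValueError("n_signal_features cannot exceed n_features")
        if min(self.n_cell_lines, self.n_drugs, self.n_features, self.latent_dim) < 1:
            raise ValueError("dimensions must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities behind a generated screen, for oracle comparisons."""

    config: GeneratorConfig
    grand_mean: float
    drug_effects: dict[str, float]          # a_j
    cell_effects: dict[str, float]          # b_i
    descriptors: dict[str, np.ndarray]      # s_j, latent — not derived from SMILES
    cell_projection: dict[str, np.ndarray]  # x_i[signal]^T W, so g = proj . s_j
    signal_features: tuple[int, ...]
    interaction_matrix: np.ndarray          # W, (n_signal_features, latent_dim)

    def interaction(self, cell_line: str, drug: str) -> float:
        return float(self.cell_projection[cell_line] @ self.descriptors[drug])

    def signal(self, cell_line: str, drug: str) -> float:
        """a_j + b_i + g — the noise-free deviation from the grand mean."""
        return (
            self.drug_effects[drug]
            + self.cell_effects[cell_line]
            + self.interaction(cell_line, drug)
        )

    def additive_oracle(self, keys) -> PredictionTable:
        """grand_mean + a_j + b_i: the best predictor ignoring the interaction."""
        return PredictionTable.from_records(
            [
                (c, d, self.grand_mean + self.drug_effects[d] + self.cell_effects[c])
                for c, d in keys
            ]
        )

    def full_oracle(self, keys) -> PredictionTable:
        """grand_mean + a_j + b_i + g: attains the sd_noise^2 floor exactly."""
        return PredictionTable.from_records(
            [(c, d, self.grand_mean + self.signal(c, d)) for c, d in keys]
        )


# ---------------------------------------------------------------------------
# SMILES generation
# ---------------------------------------------------------------------------

_CHAIN_ATOMS = ["C", "C", "C", "C", "N", "O", "S"]
_BRANCHES = ["(C)", "(N)", "(O)", "(=O)", "(Cl)", "(F)"]
_MOTIFS = ["c1ccccc1", "C1CCCCC1", "c1ccncc1"]


def _random_smiles(rng: np.random.Generator) -> str:
    parts: list[str] = []
    if rng.random() < 0.6:
        parts.append(str(rng.choice(_MOTIFS)))
    for _ in range(int(rng.integers(4, 14))):
        parts.append(str(rng.choice(_CHAIN_ATOMS)))
        if rng.random() < 0.25:
            parts.append(str(rng.choice(_BRANCHES)))
    if rng.random() < 0.3:
        parts.append(str(rng.choice(["Cl", "F", "Br"])))
    return "".join(parts)


def generate_smiles(n_drugs: int, seed: int = 0) -> DrugSet:
    """`n_drugs` distinct, tokenizable SMILES-like strings over a template grammar."""
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    rng = np.random.default_rng(seed)
    smiles: dict[str, str] = {}
    seen: set[str] = set()
    for j in range(n_drugs):
        s = _random_smiles(rng)
        while s in seen:
            s = s + "C"  # disambiguate rare collisions deterministically
        seen.add(s)
        smiles[f"d{j:04d}"] = s
    return DrugSet(drug_ids=tuple(smiles), smiles=smiles)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _informative_smiles(s: np.ndarray, rng: np.random.Generator) -> str:
    """Encode the leading descriptor components in the atom composition.

    Mean-pooled token embeddings see composition *fractions*, so the nitrogen,
    oxygen and chlorine fractions carry s[0], s[1], s[2] respectively.
    """
    n_heavy = 18
    n_n = int(round(0.5 * n_heavy * _sigmoid(float(s[0]))))
    n_o = int(round(0.4 * n_heavy * _sigmoid(float(s[1])))) if len(s) > 1 else 0
    n_cl = int(round(3 * _sigmoid(float(s[2])))) if len(s) > 2 else 0
    n_c = max(n_heavy - n_n - n_o, 2)
    atoms = ["C"] * n_c + ["N"] * n_n + ["O"] * n_o
    rng.shuffle(atoms)
    chain = list(atoms)
    for _ in range(n_cl):  # halogens as branches off the leading carbons
        chain.insert(1, "(Cl)")
    return "".join(chain)


# ---------------------------------------------------------------------------
# screen generation
# ---------------------------------------------------------------------------

def generate_screen(
    config: GeneratorConfig,
) -> tuple[ResponseTable, OmicsMatrix, DrugSet, GroundTruth]:
    """Draw one screen: responses, omics profiles, drugs, and its ground truth."""
    rng = np.random.default_rng(config.seed)
    cells = [f"c{i:04d}" for i in range(config.n_cell_lines)]
    drugs = [f"d{j:04d}" for j in range(config.n_drugs)]

    a = rng.normal(0.0, config.sd_drug_effect, size=config.n_drugs)
    b = rng.normal(0.0, config.sd_cell_effect, size=config.n_cell_lines)
    X = rng.normal(0.0, 1.0, size=(config.n_cell_lines, config.n_features))
    signal_idx = np.sort(rng.choice(config.n_features, config.n_signal_features, replace=False))
    S = rng.normal(0.0, 1.0, size=(config.n_drugs, config.latent_dim))
    W0 = rng.normal(0.0, 1.0, size=(config.n_signal_features, config.latent_dim))
    if config.sd_interaction > 0:
        W = config.sd_interaction * W0 / np.linalg.norm(W0)
    else:
        W = np.zeros_like(W0)
    proj = X[:, signal_idx] @ W  # (cells, latent)
    G = proj @ S.T  # (cells, drugs)
    eps = rng.normal(0.0, config.sd_noise, size=(config.n_cell_lines, config.n_drugs))
    Y = config.grand_mean + a[None, :] + b[:, None] + G + eps
    observed = rng.random((config.n_cell_lines, config.n_drugs)) >= config.missing_fraction
    if not observed.any():
        raise ValueError("all pairs were dropped; lower missing_fraction")

    records = [
        (cells[i], drugs[j], float(Y[i, j]))
        for i in range(config.n_cell_lines)
        for j in range(config.n_drugs)
        if observed[i, j]
    ]
    table = ResponseTable.from_records(records, value_kind=ValueKind.continuous_lnIC50)

    omics = OmicsMatrix(
        cell_line_ids=tuple(cells),
        feature_ids=tuple(f"g{k:04d}" for k in range(config.n_features)),
        values=X,
        omics_kind=OmicsKind.transcriptomics,
    )

    smiles_rng = np.random.default_rng(config.seed + 7919)
    if config.smiles_informative:
        smiles = {d: _informative_smiles(S[j], smiles_rng) for j, d in enumerate(drugs)}
    else:
        smiles = {d: _random_smiles(smiles_rng) for d in drugs}
    drug_set = DrugSet(drug_ids=tuple(drugs), smiles=smiles)

    gt = GroundTruth(
        config=config,
        grand_mean=config.grand_mean,
        drug_effects={d: float(a[j]) for j, d in enumerate(drugs)},
        cell_effects={c: float(b[i]) for i, c in enumerate(cells)},
        descriptors={d: S[j].copy() for j, d in enumerate(drugs)},
        cell_projection={c: proj[i].copy() for i, c in enumerate(cells)},
        signal_features=tuple(int(k) for k in signal_idx),
        interaction_matrix=W,
    )
    return table, omics, drug_set, gt


def inject_binarizable_structure(table: ResponseTable, gt: GroundTruth) -> ResponseTable:
    """Redraw the noise so the *sign* of a_j + b_i + g survives it.

    The replacement noise keeps variance ~ sd_noise^2 but is partially aligned
    with the sign of the noise-free signal, so thresholding at the grand mean
    flips far fewer labels than the raw draw would — binary labels carry a
    higher signal-to-noise ratio than the continuous values.  The map is
    per-record (keyed by sorted (cell, drug)), so record order is irrelevant.
    """
    # lam < 0.5 keeps sign flips possible (agreement still degrades with noise)
    # while making them rarer than under a symmetric draw of the same variance
    lam = 0.35
    # Var(lam*|z|*sign + (1-lam)*z) = lam^2 + (1-lam)^2 for z ~ N(0,1)
    scale = gt.config.sd_noise / np.sqrt(lam**2 + (1 - lam) ** 2)
    rng = np.random.default_rng(gt.config.seed + 1_000_003)
    order = sorted(table.keys)
    z = rng.normal(0.0, 1.0, size=len(order))
    new_values: dict[tuple[str, str], float] = {}
    for (c, d), zi in zip(order, z):
        sig = gt.signal(c, d)
        aligned = lam * abs(zi) * np.sign(sig) + (1 - lam) * zi
        new_values[(c, d)] = gt.grand_mean + sig + scale * aligned
    df = table.records
    out = pd.DataFrame(
        {
            "cell_line": df["cell_line"],
            "drug": df["drug"],
            "value": [new_values[k] for k in zip(df["cell_line"], df["drug"])],
        }
    )
    return ResponseTable(out, value_kind=ValueKind.continuous_lnIC50)
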