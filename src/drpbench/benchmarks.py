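"""Canonical desk-scale benchmark conditions.

These frozen configurations define the package's default synthetic
benchmarks — the conditions under which the qualitative findings are
asserted.  They are study conditions, not tuning knobs: the ablation
benchmark puts most of the within-drug label variance into a
chemistry-borne interaction (so a drug branch *can* matter), while the
mixed-set null benchmark has no interaction at all (so nothing beyond the
training truth values is learnable).
"""

from __future__ import annotations

from .baselines import MarkerBaselineConfig
from .data_model import PredictionScale
from .models import ModelConfig
from .synthetic import GeneratorConfig

__all__ = [
    "ablation_benchmark_config",
    "mixed_set_null_config",
    "desk_scale_model_config",
    "desk_scale_marker_config",
]


def ablation_benchmark_config(interaction: bool = True, seed: int = 11) -> GeneratorConfig:
    """Cancer-blind ablation benchmark: binarized targets, chemistry-borne signal.

    With ``interaction=True``, 2.0 sd of bilinear omics x descriptor signal is
    encoded in the SMILES composition; with ``False`` the same screen carries
    no interaction, so the drug branch has nothing real to learn.
    """
    return GeneratorConfig(
        n_cell_lines=150,
        n_drugs=40,
        n_features=20,
        n_signal_features=5,
        latent_dim=3,
        missing_fraction=0.3,
        sd_drug_effect=1.0,
        sd_cell_effect=0.3,
        sd_interaction=2.0 if interaction else 0.0,
        sd_noise=0.3,
        grand_mean=0.0,
        smiles_informative=True,
        seed=seed,
    )


def mixed_set_null_config(seed: int = 7) -> GeneratorConfig:
    """Mixed-set benchmark with main effects and noise only (no interaction)."""
    return GeneratorConfig(
        n_cell_lines=100,
        n_drugs=30,
        n_features=20,
        n_signal_features=5,
        latent_dim=3,
        missing_fraction=0.15,
        sd_drug_effect=2.0,
        sd_cell_effect=1.0,
        sd_interaction=0.0,
        sd_noise=0.5,
        grand_mean=2.5,
        smiles_informative=False,
        seed=seed,
    )


def desk_scale_model_config(
    output: PredictionScale = PredictionScale.continuous, model_seed: int = 0
) -> ModelConfig:
    """Reduced-width two-branch model sized for the desk-scale benchmarks."""
    return ModelConfig(
        cell_hidden=(64, 32),
        cell_embed_dim=16,
        d_model=32,
        n_encoder_layers=1,
        n_heads=4,
        ff_dim=64,
        fusion_hidden=(64, 32),
        output=PredictionScale(output),
        max_epochs=80 if output == PredictionScale.probability else 100,
        patience=15,
        batch_size=256,
        learning_rate=1e-3,
        model_seed=model_seed,
    )


def desk_scale_marker_config(model_seed: int = 0) -> MarkerBaselineConfig:
    return MarkerBaselineConfig(
        hidden=(128, 128), max_epochs=150, patience=20, seed=model_seed
    )
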