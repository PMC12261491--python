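import numpy as np
import pytest

from drpbench import (
    Ablation,
    BinarizationRule,
    DrugBranchKind,
    GeneratorConfig,
    ModelConfig,
    OmicsMatrix,
    PredictionScale,
    binarize,
    build_model,
    generate_screen,
    make_split,
    predict,
    train,
    variant,
)
from drpbench.tokenizer import (
    SmilesVocabulary,
    detokenize,
    split_smiles,
    tokenize_smiles,
)


class TestTokenizer:
    VOCAB = SmilesVocabulary.build(["CCO", "c1ccccc1Cl", "CC(=O)N", "C[nH]Br"])

    def test_single_character_atoms(self):
        tok = tokenize_smiles("CCO", self.VOCAB)
        ids = tok.token_ids[: tok.length]
        names = [self.VOCAB.id_to_token()[int(i)] for i in ids]
        assert names == ["<cls>", "C", "C", "O"]

    def test_two_letter_element_is_one_token(self):
        assert split_smiles("c1ccccc1Cl")[-1] == "Cl"
        assert "l" not in split_smiles("c1ccccc1Cl")

    def test_bracket_atom_is_one_token(self):
        assert "[nH]" in split_smiles("C[nH]Br")

    def test_round_trip(self):
        for s in ("CC(=O)N", "c1ccccc1Cl", "C[nH]Br"):
            tok = tokenize_smiles(s, self.VOCAB)
            assert detokenize(tok, self.VOCAB) == s

    def test_unknown_characters_map_to_unk(self):
        tok = tokenize_smiles("CXC", self.VOCAB)
        assert tok.n_unknown == 1

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            split_smiles("")

    def test_truncation_to_max_len(self):
        tok = tokenize_smiles("C" * 50, self.VOCAB, max_len=10)
        assert tok.length == 10 and tok.token_ids.shape == (10,)


@pytest.fixture(scope="module")
def screen():
    cfg = GeneratorConfig(
        n_cell_lines=20, n_drugs=8, n_features=10, n_signal_features=3,
        missing_fraction=0.0, sd_drug_effect=1.0, sd_cell_effect=1.0,
        sd_interaction=0.0, sd_noise=0.0, grand_mean=0.0, seed=1,
    )
    return generate_screen(cfg)


SMALL = ModelConfig(
    cell_hidden=(32, 16), cell_embed_dim=8, d_model=16, n_encoder_layers=1,
    n_heads=2, ff_dim=32, fusion_hidden=(32, 16), max_epochs=5,
    batch_size=64, model_seed=0,
)


class TestArchitecture:
    def test_parameter_count_matches_closed_form(self, screen):
        _, omics, drugs, _ = screen
        model = build_model(SMALL, omics, drugs)
        n_feat = len(omics.feature_ids)
        V = len(model.vocabulary)
        d, ff = SMALL.d_model, SMALL.ff_dim
        cell = (n_feat * 32 + 32) + (32 * 16 + 16) + (16 * 8 + 8)
        embed = V * d + SMALL.max_smiles_len * d
        attn = 4 * (d * d + d)
        ffn = (d * ff + ff) + (ff * d + d)
        norms = 2 * (2 * d)
        encoder = embed + SMALL.n_encoder_layers * (attn + ffn + norms)
        fusion = ((8 + d) * 32 + 32) + (32 * 16 + 16) + (16 * 1 + 1)
        assert model.n_parameters() == cell + encoder + fusion

    def test_minus_drug_branch_shape(self, screen):
        _, omics, drugs, _ = screen
        cfg = variant(SMALL, Ablation.minus_drug_branch)
        model = build_model(cfg, omics, drugs)
        assert model.drug_encoder is None
        assert model.drug_dim == len(drugs)
        # fusion input = cell embedding + one-hot drug dimension
        assert model.fusion.layers[0].weight.shape[0] == 8 + len(drugs)

    def test_all_marker_has_no_omics_path(self, screen):
        table, omics, drugs, _ = screen
        cfg = variant(SMALL, Ablation.all_marker)
        model = build_model(cfg, omics, drugs)
        keys = table.keys[:5]
        before = model.predict_values(keys)
        perturbed = OmicsMatrix(
            omics.cell_line_ids, omics.feature_ids,
            omics.values + 100.0, omics.omics_kind,
        )
        model.omics = perturbed
        after = model.predict_values(keys)
        np.testing.assert_array_equal(before, after)

    def test_dimension_validation(self, screen):
        _, omics, drugs, _ = screen
        with pytest.raises(ValueError):
            build_model(
                ModelConfig(d_model=10, n_heads=4), omics, drugs
            )  # d_model not divisible by heads


class TestTraining:
    def test_overfits_tiny_noiseless_screen(self):
        cfg = GeneratorConfig(
            n_cell_lines=15, n_drugs=8, n_features=10, n_signal_features=2,
            missing_fraction=0.0, sd_drug_effect=1.0, sd_cell_effect=1.0,
            sd_interaction=0.0, sd_noise=0.0, grand_mean=0.0, seed=1,
        )
        table, omics, drugs, _ = generate_screen(cfg)
        sp = make_split(table, "mixed_set", seed=0)
        mc = ModelConfig(
            cell_hidden=(32, 16), cell_embed_dim=8, d_model=16, n_encoder_layers=1,
            n_heads=2, ff_dim=32, fusion_hidden=(32, 16), max_epochs=500,
            patience=500, batch_size=64, learning_rate=3e-3, model_seed=0,
        )
        run = train(build_model(mc, omics, drugs), sp, table)
        assert min(run.train_losses) < 1e-2

    def test_fixed_seeds_reproduce_run_exactly(self, screen):
        table, omics, drugs, _ = screen
        sp = make_split(table, "mixed_set", seed=0)
        runs = [train(build_model(SMALL, omics, drugs), sp, table) for _ in range(2)]
        assert runs[0].selected_epoch == runs[1].selected_epoch
        assert runs[0].val_losses == runs[1].val_losses
        np.testing.assert_array_equal(
            runs[0].test_predictions.records["prediction"],
            runs[1].test_predictions.records["prediction"],
        )

    def test_probability_output_bounds_and_kind_checks(self, screen):
        table, omics, drugs, _ = screen
        btable = binarize(table, BinarizationRule("per_drug_mean"))
        sp = make_split(btable, "mixed_set", seed=0)
        mc_prob = ModelConfig(**{**SMALL.__dict__, "output": PredictionScale.probability})
        run = train(build_model(mc_prob, omics, drugs), sp, btable)
        preds = run.test_predictions.records["prediction"]
        assert (preds >= 0).all() and (preds <= 1).all()
        # mismatched target/output kinds are rejected both ways
        with pytest.raises(ValueError, match="binary"):
            train(build_model(mc_prob, omics, drugs), sp, table)
        with pytest.raises(ValueError, match="continuous"):
            train(build_model(SMALL, omics, drugs), sp, btable)


class TestPredict:
    def test_permutation_and_duplication_consistency(self, screen):
        table, omics, drugs, _ = screen
        model = build_model(SMALL, omics, drugs)
        keys = table.keys[:6]
        p1 = predict(model, keys).prediction_map()
        p2 = predict(model, list(reversed(keys))).prediction_map()
        assert p1 == pytest.approx(p2)
        dup = predict(model, [keys[0], keys[0]])
        vals = dup.records["prediction"]
        assert vals.iloc[0] == vals.iloc[1]

    def test_same_drug_different_cells_vary_through_cell_pathway(self, screen):
        table, omics, drugs, _ = screen
        model = build_model(SMALL, omics, drugs)
        d = drugs.drug_ids[0]
        cells = omics.cell_line_ids[:4]
        vals = predict(model, [(c, d) for c in cells]).records["prediction"]
        assert len(set(np.round(vals, 12))) > 1

    def test_missing_entity_named_in_error(self, screen):
        _, omics, drugs, _ = screen
        model = build_model(SMALL, omics, drugs)
        with pytest.raises(KeyError, match="zz"):
            predict(model, [("zz", drugs.drug_ids[0])])
        with pytest.raises(KeyError, match="nope"):
            predict(model, [(omics.cell_line_ids[0], "nope")])
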