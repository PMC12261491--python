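import numpy as np
import pandas as pd
import pytest

from drpbench import (
    BinarizationRule,
    GeneratorConfig,
    binarize,
    generate_screen,
    generate_smiles,
    inject_binarizable_structure,
    metric_unstratified,
)
from drpbench.tokenizer import SmilesVocabulary, tokenize_smiles, detokenize


class TestGenerateScreen:
    def test_pure_drug_effect_is_exact(self):
        cfg = GeneratorConfig(
            n_cell_lines=8, n_drugs=4, n_features=5, n_signal_features=2,
            missing_fraction=0.0, sd_cell_effect=0.0, sd_interaction=0.0,
            sd_noise=0.0, grand_mean=0.0, seed=1,
        )
        table, _, _, gt = generate_screen(cfg)
        for (c, d), v in table.value_map().items():
            assert v == pytest.approx(gt.drug_effects[d], abs=1e-12)

    def test_complete_matrix_record_count(self):
        cfg = GeneratorConfig(n_cell_lines=10, n_drugs=5, n_features=5,
                              n_signal_features=1, missing_fraction=0.0, seed=0)
        table, _, _, _ = generate_screen(cfg)
        assert len(table) == 50

    def test_per_drug_mean_variance_matches_drug_effect(self):
        # Monte-Carlo check of the variance decomposition at 200 x 200
        cfg = GeneratorConfig(
            n_cell_lines=200, n_drugs=200, n_features=5, n_signal_features=1,
            missing_fraction=0.0, sd_drug_effect=2.0, sd_cell_effect=0.0,
            sd_interaction=0.0, sd_noise=1.0, grand_mean=0.0, seed=3,
        )
        table, _, _, _ = generate_screen(cfg)
        per_drug = table.records.groupby("drug")["value"].mean()
        assert np.var(per_drug, ddof=1) == pytest.approx(4.0, rel=0.15)

    def test_drug_dummy_regression_recovers_variance_share(self):
        # R^2 of the drug-indicator model ~ sd_drug^2 / total variance
        cfg = GeneratorConfig(
            n_cell_lines=120, n_drugs=100, n_features=5, n_signal_features=1,
            missing_fraction=0.1, sd_drug_effect=2.0, sd_cell_effect=0.5,
            sd_interaction=0.0, sd_noise=1.0, grand_mean=1.0, seed=4,
        )
        table, _, _, _ = generate_screen(cfg)
        df = table.records
        ss_tot = np.sum((df["value"] - df["value"].mean()) ** 2)
        resid = df["value"] - df.groupby("drug")["value"].transform("mean")
        r2 = 1 - np.sum(resid**2) / ss_tot
        expected = 4.0 / (4.0 + 0.25 + 1.0)
        assert r2 == pytest.approx(expected, abs=0.05)

    def test_full_oracle_attains_noise_floor(self):
        cfg = GeneratorConfig(
            n_cell_lines=100, n_drugs=40, n_features=10, n_signal_features=3,
            missing_fraction=0.0, sd_drug_effect=2.0, sd_cell_effect=1.0,
            sd_interaction=0.8, sd_noise=0.6, seed=5,
        )
        table, _, _, gt = generate_screen(cfg)
        mse = metric_unstratified(gt.full_oracle(table.keys), table, "mse")
        assert mse == pytest.approx(0.36, rel=0.1)

    def test_interaction_variance_scaling(self):
        cfg = GeneratorConfig(
            n_cell_lines=300, n_drugs=100, n_features=10, n_signal_features=4,
            missing_fraction=0.0, sd_drug_effect=0.0, sd_cell_effect=0.0,
            sd_interaction=1.5, sd_noise=0.0, grand_mean=0.0, seed=6,
        )
        table, _, _, _ = generate_screen(cfg)
        assert np.var(table.records["value"]) == pytest.approx(1.5**2, rel=0.2)

    def test_determinism(self):
        cfg = GeneratorConfig(n_cell_lines=12, n_drugs=6, seed=9)
        t1, o1, d1, g1 = generate_screen(cfg)
        t2, o2, d2, g2 = generate_screen(cfg)
        pd.testing.assert_frame_equal(t1.records, t2.records)
        np.testing.assert_array_equal(o1.values, o2.values)
        assert d1.smiles == d2.smiles
        assert g1.drug_effects == g2.drug_effects

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(missing_fraction=1.0)
        with pytest.raises(ValueError):
            GeneratorConfig(sd_noise=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(n_features=3, n_signal_features=4)


class TestGenerateSmiles:
    def test_distinct_and_reproducible(self):
        a = generate_smiles(50, seed=13)
        b = generate_smiles(50, seed=13)
        assert len(set(a.smiles.values())) == 50
        assert a.smiles == b.smiles
        assert generate_smiles(50, seed=14).smiles != a.smiles

    def test_single_drug_nonempty(self):
        d = generate_smiles(1, seed=0)
        assert len(d) == 1 and len(next(iter(d.smiles.values()))) > 0

    def test_all_outputs_tokenize_without_unknowns(self):
        drugs = generate_smiles(60, seed=2)
        vocab = SmilesVocabulary.build(list(drugs.smiles.values()))
        for s in drugs.smiles.values():
            tok = tokenize_smiles(s, vocab)
            assert tok.n_unknown == 0
            assert detokenize(tok, vocab) == s


class TestInjectBinarizableStructure:
    @staticmethod
    def _agreement(sd_noise: float) -> float:
        cfg = GeneratorConfig(
            n_cell_lines=80, n_drugs=25, n_features=5, n_signal_features=2,
            missing_fraction=0.0, sd_drug_effect=1.0, sd_cell_effect=0.8,
            sd_interaction=0.5, sd_noise=sd_noise, grand_mean=0.0, seed=21,
        )
        table, _, _, gt = generate_screen(cfg)
        injected = inject_binarizable_structure(table, gt)
        agree = [
            (v < gt.grand_mean) == (gt.signal(c, d) < 0)
            for (c, d), v in injected.value_map().items()
        ]
        return float(np.mean(agree))

    def test_zero_noise_recovers_sign_exactly(self):
        assert self._agreement(0.0) == 1.0

    def test_agreement_decreases_with_noise(self):
        levels = [self._agreement(s) for s in (0.3, 1.0, 3.0)]
        assert levels[0] > levels[1] > levels[2]

    def test_record_order_invariance(self):
        cfg = GeneratorConfig(n_cell_lines=10, n_drugs=5, missing_fraction=0.0, seed=8)
        table, _, _, gt = generate_screen(cfg)
        shuffled = table.subset(list(reversed(table.keys)))
        a = inject_binarizable_structure(table, gt).value_map()
        b = inject_binarizable_structure(shuffled, gt).value_map()
        assert a == pytest.approx(b)

    def test_binarized_labels_cleaner_than_raw_noise(self):
        # the redrawn noise must flip fewer signs than a symmetric draw would
        cfg = GeneratorConfig(
            n_cell_lines=100, n_drugs=30, n_features=5, n_signal_features=2,
            missing_fraction=0.0, sd_drug_effect=1.0, sd_cell_effect=0.5,
            sd_interaction=0.4, sd_noise=0.8, grand_mean=0.0, seed=30,
        )
        table, _, _, gt = generate_screen(cfg)
        injected = inject_binarizable_structure(table, gt)
        raw_agree = np.mean(
            [(v < 0) == (gt.signal(c, d) < 0) for (c, d), v in table.value_map().items()]
        )
        inj_agree = np.mean(
            [(v < 0) == (gt.signal(c, d) < 0) for (c, d), v in injected.value_map().items()]
        )
        assert inj_agree > raw_agree
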