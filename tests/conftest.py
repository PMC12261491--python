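import numpy as np
import pytest

from drpbench import (
    GeneratorConfig,
    ResponseTable,
    ValueKind,
    generate_screen,
)


@pytest.fixture
def tiny_table() -> ResponseTable:
    return ResponseTable.from_records(
        [
            ("c1", "d1", 2.0),
            ("c1", "d2", 4.0),
            ("c2", "d1", -1.0),
            ("c2", "d2", 0.5),
            ("c3", "d1", 3.0),
            ("c3", "d2", 1.5),
        ]
    )


@pytest.fixture(scope="session")
def small_screen():
    """A 40 cells x 12 drugs screen with all variance components active."""
    config = GeneratorConfig(
        n_cell_lines=40,
        n_drugs=12,
        n_features=15,
        n_signal_features=4,
        latent_dim=3,
        missing_fraction=0.1,
        sd_drug_effect=1.5,
        sd_cell_effect=0.8,
        sd_interaction=0.6,
        sd_noise=0.5,
        grand_mean=2.0,
        seed=42,
    )
    return generate_screen(config)


def random_response_table(
    rng: np.random.Generator,
    n_cells: int | None = None,
    n_drugs: int | None = None,
    missing: float | None = None,
) -> ResponseTable:
    """A random dense-ish continuous table for property tests."""
    n_cells = n_cells or int(rng.integers(5, 15))
    n_drugs = n_drugs or int(rng.integers(4, 12))
    missing = missing if missing is not None else float(rng.uniform(0.0, 0.3))
    records = []
    for i in range(n_cells):
        for j in range(n_drugs):
            if rng.random() >= missing:
                records.append((f"c{i}", f"d{j}", float(rng.normal(0, 2))))
    if not records:
        records = [("c0", "d0", 0.0)]
    return ResponseTable.from_records(records, value_kind=ValueKind.continuous_lnIC50)
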