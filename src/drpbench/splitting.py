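"""Train/validation/test construction for the three DRP evaluation regimes.

* ``mixed_set`` — the (cell line, drug) *pairs* are partitioned at random;
  every test drug and cell line also occurs in training (orphan test pairs
  are repaired into the training set, with a count).
* ``cancer_blind`` — the *cell lines* are partitioned; no cell line appears
  in more than one of train/validation/test, while drugs span all sets.
* ``drug_blind`` — likewise over drugs; cell lines span all sets.

Blind-regime fractions apply to the entity count (whole matrix rows/columns
change set), with floor rounding for validation and test and the remainder
to train.  Mixed-set fractions apply to pairs.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import ResponseTable

__all__ = ["Regime", "SplitAssignment", "make_split", "verify_split", "save_split", "load_split"]

logger = logging.getLogger(__name__)

Key = tuple[str, str]


class Regime(str, enum.Enum):
    mixed_set = "mixed_set"
    cancer_blind = "cancer_blind"
    drug_blind = "drug_blind"


@dataclass(frozen=True)
class SplitAssignment:
    regime: Regime
    train: tuple[Key, ...]
    validation: tuple[Key, ...]
    test: tuple[Key, ...]
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    split_seed: int = 0
    n_repaired_test: int = 0
    n_repaired_validation: int = 0

    @property
    def train_cell_lines(self) -> set[str]:
        return {c for c, _ in self.train}

    @property
    def train_drugs(self) -> set[str]:
        return {d for _, d in self.train}

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def _check_fractions(fractions: tuple[float, float, float]) -> None:
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")


def _entity_partition(
    entities: list[str], fractions: tuple[float, float, float], rng: np.random.Generator
) -> tuple[set[str], set[str], set[str]]:
    order = list(rng.permutation(entities))
    n = len(order)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    return (
        set(order[:n_train]),
        set(order[n_train : n_train + n_val]),
        set(order[n_train + n_val :]),
    )


def make_split(
    table: ResponseTable,
    regime: Regime | str,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Deterministically partition a response table's keys under one regime."""
    regime = Regime(regime)
    _check_fractions(fractions)
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(seed)
    keys = table.keys

    if regime == Regime.mixed_set:
        order = [keys[i] for i in rng.permutation(len(keys))]
        n = len(order)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_val = min(n_val, n - n_train)
        train = order[:n_train]
        validation = order[n_train : n_train + n_val]
        test = order[n_train + n_val :]
        # coverage repair: every evaluation entity must occur in training so
        # the marker baseline (and per-entity means) are well-defined
        n_rep_test = n_rep_val = 0
        changed = True
        while changed:
            changed = False
            cells = {c for c, _ in train}
            drugs = {d for _, d in train}
            keep_t, keep_v = [], []
            for c, d in test:
                if c not in cells or d not in drugs:
                    train.append((c, d))
                    n_rep_test += 1
                    changed = True
                else:
                    keep_t.append((c, d))
            test = keep_t
            cells = {c for c, _ in train}
            drugs = {d for _, d in train}
            for c, d in validation:
                if c not in cells or d not in drugs:
                    train.append((c, d))
                    n_rep_val += 1
                    changed = True
                else:
                    keep_v.append((c, d))
            validation = keep_v
        if n_rep_test or n_rep_val:
            logger.info(
                "mixed_set coverage repair moved %d test and %d validation pairs to train",
                n_rep_test,
                n_rep_val,
            )
        return SplitAssignment(
            regime=regime,
            train=tuple(train),
            validation=tuple(validation),
            test=tuple(test),
            fractions=tuple(fractions),
            split_seed=seed,
            n_repaired_test=n_rep_test,
            n_repaired_validation=n_rep_val,
        )

    if regime == Regime.cancer_blind:
        entities = table.cell_lines
        if len(entities) < 3:
            raise ValueError("cancer_blind split needs at least 3 cell lines")
        tr, va, te = _entity_partition(entities, fractions, rng)
        pick = lambda bucket: tuple(k for k in keys if k[0] in bucket)
    else:  # drug_blind
        entities = table.drugs
        if len(entities) < 3:
            raise ValueError("drug_blind split needs at least 3 drugs")
        tr, va, te = _entity_partition(entities, fractions, rng)
        pick = lambda bucket: tuple(k for k in keys if k[1] in bucket)

    return SplitAssignment(
        regime=regime,
        train=pick(tr),
        validation=pick(va),
        test=pick(te),
        fractions=tuple(fractions),
        split_seed=seed,
    )


def verify_split(assignment: SplitAssignment, table: ResponseTable) -> dict[str, dict]:
    """Check the regime invariants; returns pass/fail per check, never raises."""
    checks: dict[str, dict] = {}
    train, val, test = set(assignment.train), set(assignment.validation), set(assignment.test)
    table_keys = set(table.keys)

    overlap = (train & val) | (train & test) | (val & test)
    exhaustive = (train | val | test) == table_keys
    checks["partition"] = {
        "passed": not overlap and exhaustive,
        "n_overlapping_pairs": len(overlap),
        "n_missing_pairs": len(table_keys - (train | val | test)),
        "n_extra_pairs": len((train | val | test) - table_keys),
    }

    def entities(keys: set[Key], idx: int) -> set[str]:
        return {k[idx] for k in keys}

    if assignment.regime == Regime.cancer_blind:
        shared = (
            (entities(train, 0) & entities(val, 0))
            | (entities(train, 0) & entities(test, 0))
            | (entities(val, 0) & entities(test, 0))
        )
        checks["cell_line_blindness"] = {
            "passed": not shared,
            "overlap_count": len(shared),
            "offending": sorted(shared)[:5],
        }
        missing = entities(test, 1) - entities(train, 1)
        checks["test_drugs_in_train"] = {"passed": not missing, "missing": sorted(missing)[:5]}
    elif assignment.regime == Regime.drug_blind:
        shared = (
            (entities(train, 1) & entities(val, 1))
            | (entities(train, 1) & entities(test, 1))
            | (entities(val, 1) & entities(test, 1))
        )
        checks["drug_blindness"] = {
            "passed": not shared,
            "overlap_count": len(shared),
            "offending": sorted(shared)[:5],
        }
        missing = entities(test, 0) - entities(train, 0)
        checks["test_cell_lines_in_train"] = {"passed": not missing, "missing": sorted(missing)[:5]}
    else:  # mixed_set: every test entity must also appear in train
        missing_c = entities(test, 0) - entities(train, 0)
        missing_d = entities(test, 1) - entities(train, 1)
        checks["test_entity_in_train"] = {
            "passed": not missing_c and not missing_d,
            "missing_cell_lines": sorted(missing_c)[:5],
            "missing_drugs": sorted(missing_d)[:5],
        }
    return checks


def save_split(assignment: SplitAssignment, path) -> None:
    payload = {
        "regime": assignment.regime.value,
        "fractions": list(assignment.fractions),
        "split_seed": assignment.split_seed,
        "n_repaired_test": assignment.n_repaired_test,
        "n_repaired_validation": assignment.n_repaired_validation,
        "train": [list(k) for k in assignment.train],
        "validation": [list(k) for k in assignment.validation],
        "test": [list(k) for k in assignment.test],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_split(path) -> SplitAssignment:
    with open(path) as fh:
        payload = json.load(fh)
    return SplitAssignment(
        regime=Regime(payload["regime"]),
        train=tuple((c, d) for c, d in payload["train"]),
        validation=tuple((c, d) for c, d in payload["validation"]),
        test=tuple((c, d) for c, d in payload["test"]),
        fractions=tuple(payload["fractions"]),
        split_seed=payload["split_seed"],
        n_repaired_test=payload.get("n_repaired_test", 0),
        n_repaired_validation=payload.get("n_repaired_validation", 0),
    )
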