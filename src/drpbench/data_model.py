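"""Core containers for drug-response screens and the delimited formats they travel in.

A screen is a sparse set of (cell line, drug) response measurements: the truth
values ``y_ij`` a drug-response-prediction (DRP) model is trained and judged on.
Cell lines carry an omics profile (a row in a samples x features matrix), drugs
carry a SMILES string.  Missing measurements are represented by *absence* of
the triplet, never by a sentinel, so per-drug / per-cell-line record counts are
unambiguous.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValueKind",
    "OmicsKind",
    "DrugRepresentation",
    "PredictionScale",
    "ResponseTable",
    "OmicsMatrix",
    "DrugSet",
    "PredictionTable",
    "FormatError",
    "read_response_table",
    "write_response_table",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_drug_set",
    "write_drug_set",
    "to_marker",
    "drug_marker_encodings",
]


class FormatError(ValueError):
    """Raised when an input file or table violates a structural invariant."""


class ValueKind(str, enum.Enum):
    continuous_lnIC50 = "continuous_lnIC50"
    binary = "binary"


class OmicsKind(str, enum.Enum):
    transcriptomics = "transcriptomics"
    genomics = "genomics"
    marker_onehot = "marker_onehot"


class DrugRepresentation(str, enum.Enum):
    smiles_tokens = "smiles_tokens"
    marker_onehot = "marker_onehot"


class PredictionScale(str, enum.Enum):
    continuous = "continuous"
    probability = "probability"


def _check_no_duplicate_pairs(cells: Sequence[str], drugs: Sequence[str]) -> None:
    seen: set[tuple[str, str]] = set()
    dupes: list[tuple[str, str]] = []
    for key in zip(cells, drugs):
        if key in seen:
            dupes.append(key)
        seen.add(key)
    if dupes:
        shown = ", ".join(f"{c},{d}" for c, d in dupes[:5])
        raise FormatError(f"duplicate (cell_line, drug) pairs: {shown}")


@dataclass(frozen=True)
class ResponseTable:
    """Sparse (cell_line, drug, value) triplets.

    Continuous values are natural-log IC50 (ln micromolar, GDSC convention);
    binary values are 1 = sensitive, 0 = resistant.
    """

    records: pd.DataFrame  # columns: cell_line, drug, value
    value_kind: ValueKind = ValueKind.continuous_lnIC50

    def __post_init__(self) -> None:
        df = self.records
        expected = ["cell_line", "drug", "value"]
        if list(df.columns) != expected:
            raise FormatError(f"response records must have columns {expected}, got {list(df.columns)}")
        if len(df) == 0:
            raise FormatError("response table is empty")
        _check_no_duplicate_pairs(df["cell_line"].tolist(), df["drug"].tolist())
        values = df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FormatError("response values must be finite")
        if self.value_kind == ValueKind.binary and not np.all(np.isin(values, (0.0, 1.0))):
            bad = values[~np.isin(values, (0.0, 1.0))][:5]
            raise FormatError(f"binary response table contains non-{{0,1}} values: {bad.tolist()}")
        # normalise dtypes once; the frame is treated as immutable afterwards
        object.__setattr__(
            self,
            "records",
            pd.DataFrame(
                {
                    "cell_line": df["cell_line"].astype(str).to_numpy(),
                    "drug": df["drug"].astype(str).to_numpy(),
                    "value": values,
                }
            ),
        )

    @classmethod
    def from_records(
        cls,
        triplets: Iterable[tuple[str, str, float]],
        value_kind: ValueKind = ValueKind.continuous_lnIC50,
    ) -> "ResponseTable":
        df = pd.DataFrame(list(triplets), columns=["cell_line", "drug", "value"])
        return cls(df, value_kind=ValueKind(value_kind))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.records["cell_line"].unique().tolist())

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug"].unique().tolist())

    @property
    def keys(self) -> list[tuple[str, str]]:
        return list(zip(self.records["cell_line"], self.records["drug"]))

    def value_map(self) -> dict[tuple[str, str], float]:
        return dict(zip(self.keys, self.records["value"]))

    def subset(self, keys: Iterable[tuple[str, str]]) -> "ResponseTable":
        """Restrict to the given (cell_line, drug) keys (order follows `keys`)."""
        vmap = self.value_map()
        keys = list(keys)
        missing = [k for k in keys if k not in vmap]
        if missing:
            raise KeyError(f"keys not present in table: {missing[:5]}")
        return ResponseTable.from_records(
            [(c, d, vmap[(c, d)]) for c, d in keys], value_kind=self.value_kind
        )


@dataclass(frozen=True)
class OmicsMatrix:
    """Cell-line profiles: a cell_lines x features real matrix.

    ``marker_onehot`` matrices encode identity only — each row is a standard
    basis vector carrying no biological content.
    """

    cell_line_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    omics_kind: OmicsKind = OmicsKind.transcriptomics

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_line_ids", tuple(str(c) for c in self.cell_line_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if values.ndim != 2:
            raise FormatError("omics values must be a 2-D matrix")
        if values.shape != (len(self.cell_line_ids), len(self.feature_ids)):
            raise FormatError(
                f"omics shape {values.shape} does not match "
                f"{len(self.cell_line_ids)} cell lines x {len(self.feature_ids)} features"
            )
        if len(set(self.cell_line_ids)) != len(self.cell_line_ids):
            raise FormatError("duplicate cell line ids in omics matrix")
        if self.omics_kind == OmicsKind.marker_onehot:
            eye_like = (values.sum(axis=1) == 1.0) & np.all((values == 0) | (values == 1), axis=1)
            if not eye_like.all():
                raise FormatError("marker_onehot rows must be standard basis vectors")

    def row(self, cell_line_id: str) -> np.ndarray:
        try:
            i = self.cell_line_ids.index(cell_line_id)
        except ValueError:
            raise KeyError(f"cell line {cell_line_id!r} not in omics matrix") from None
        return self.values[i]

    def rows(self, cell_line_ids: Sequence[str]) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.cell_line_ids)}
        missing = [c for c in cell_line_ids if c not in index]
        if missing:
            raise KeyError(f"cell lines not in omics matrix: {missing[:5]}")
        return self.values[[index[c] for c in cell_line_ids]]


@dataclass(frozen=True)
class DrugSet:
    """Drugs with their SMILES strings (or pure one-hot marker identity)."""

    drug_ids: tuple[str, ...]
    smiles: Mapping[str, str] = field(default_factory=dict)
    representation_kind: DrugRepresentation = DrugRepresentation.smiles_tokens

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_ids", tuple(str(d) for d in self.drug_ids))
        object.__setattr__(self, "smiles", dict(self.smiles))
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise FormatError("duplicate drug ids")
        if self.representation_kind == DrugRepresentation.smiles_tokens:
            missing = [d for d in self.drug_ids if not self.smiles.get(d)]
            if missing:
                raise FormatError(f"drugs without a SMILES string: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.drug_ids)

    def smiles_for(self, drug_id: str) -> str:
        if drug_id not in self.smiles:
            raise KeyError(f"drug {drug_id!r} has no SMILES")
        return self.smiles[drug_id]


@dataclass(frozen=True)
class PredictionTable:
    """Model outputs aligned to an evaluation set's (cell_line, drug) keys."""

    records: pd.DataFrame  # columns: cell_line, drug, prediction
    scale: PredictionScale = PredictionScale.continuous

    def __post_init__(self) -> None:
        df = self.records
        expected = ["cell_line", "drug", "prediction"]
        if list(df.columns) != expected:
            raise FormatError(f"prediction records must have columns {expected}")
        preds = df["prediction"].to_numpy(dtype=float)
        if not np.all(np.isfinite(preds)):
            raise FormatError("predictions must be finite")
        if self.scale == PredictionScale.probability and (preds.min() < 0 or preds.max() > 1):
            raise FormatError("probability-scale predictions must lie in [0, 1]")
        object.__setattr__(
            self,
            "records",
            pd.DataFrame(
                {
                    "cell_line": df["cell_line"].astype(str).to_numpy(),
                    "drug": df["drug"].astype(str).to_numpy(),
                    "prediction": preds,
                }
            ),
        )

    @classmethod
    def from_records(
        cls,
        triplets: Iterable[tuple[str, str, float]],
        scale: PredictionScale = PredictionScale.continuous,
    ) -> "PredictionTable":
        df = pd.DataFrame(list(triplets), columns=["cell_line", "drug", "prediction"])
        return cls(df, scale=PredictionScale(scale))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def keys(self) -> list[tuple[str, str]]:
        return list(zip(self.records["cell_line"], self.records["drug"]))

    def prediction_map(self) -> dict[tuple[str, str], float]:
        return dict(zip(self.keys, self.records["prediction"]))


# ---------------------------------------------------------------------------
# Delimited I/O.  CSV with a header row is the default; TSV via delimiter="\t".
# ---------------------------------------------------------------------------

def read_response_table(
    path, value_kind: ValueKind = ValueKind.continuous_lnIC50, delimiter: str = ","
) -> ResponseTable:
    """Read a `cell_line,drug,value` file into a validated :class:`ResponseTable`."""
    df = pd.read_csv(path, sep=delimiter, dtype={"cell_line": str, "drug": str})
    required = {"cell_line", "drug", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected header columns {sorted(required)}, got {list(df.columns)}")
    return ResponseTable(df[["cell_line", "drug", "value"]], value_kind=ValueKind(value_kind))


def write_response_table(table: ResponseTable, path, delimiter: str = ",") -> None:
    table.records.to_csv(path, sep=delimiter, index=False)


def read_omics_matrix(
    path, omics_kind: OmicsKind = OmicsKind.transcriptomics, delimiter: str = ","
) -> OmicsMatrix:
    """Read an omics file: first column cell line id, remaining columns features."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return OmicsMatrix(
        cell_line_ids=tuple(df.index.astype(str)),
        feature_ids=tuple(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        omics_kind=OmicsKind(omics_kind),
    )


def write_omics_matrix(matrix: OmicsMatrix, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.cell_line_ids), columns=list(matrix.feature_ids))
    df.index.name = "cell_line"
    df.to_csv(path, sep=delimiter)


def read_drug_set(path, delimiter: str = ",") -> DrugSet:
    """Read a two-column `drug,smiles` file."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if not {"drug", "smiles"}.issubset(df.columns):
        raise FormatError(f"{path}: expected header columns ['drug', 'smiles']")
    return DrugSet(
        drug_ids=tuple(df["drug"]),
        smiles=dict(zip(df["drug"], df["smiles"])),
    )


def write_drug_set(drugs: DrugSet, path, delimiter: str = ",") -> None:
    pd.DataFrame(
        {"drug": list(drugs.drug_ids), "smiles": [drugs.smiles.get(d, "") for d in drugs.drug_ids]}
    ).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Marker (one-hot) encodings: identity without biology or chemistry.
# ---------------------------------------------------------------------------

def to_marker(ids: Sequence[str]) -> OmicsMatrix:
    """One-hot encode cell-line ids: the |ids| x |ids| identity with labelled rows."""
    ids = [str(i) for i in ids]
    if len(ids) == 0:
        raise ValueError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    return OmicsMatrix(
        cell_line_ids=tuple(ids),
        feature_ids=tuple(f"marker:{i}" for i in ids),
        values=np.eye(len(ids)),
        omics_kind=OmicsKind.marker_onehot,
    )


def drug_marker_encodings(ids: Sequence[str]) -> dict[str, np.ndarray]:
    """One-hot encode drug ids; rows are mutually orthogonal basis vectors."""
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if len(ids) == 0:
        raise ValueError("ids must be non-empty")
    eye = np.eye(len(ids))
    return {d: eye[i] for i, d in enumerate(ids)}
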