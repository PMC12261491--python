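"""A self-contained SMILES tokenizer: greedy longest-match over a chemistry-aware
token inventory, with a vocabulary built from the drugs at hand.

Multi-character lexemes (two-letter elements such as ``Cl``/``Br``, bracket
atoms ``[nH]``, two-digit ring closures ``%12``, stereo ``@@``) are matched
before single characters, so ``c1ccccc1Cl`` ends in one ``Cl`` token rather
than ``C`` + ``l``.  Concatenating the matched tokens (specials excluded)
reproduces the input string exactly for in-inventory input, which is the
round-trip property the tests pin down.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PAD_TOKEN", "UNK_TOKEN", "CLS_TOKEN", "SmilesVocabulary", "TokenizedDrug",
           "split_smiles", "tokenize_smiles", "detokenize"]

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
CLS_TOKEN = "<cls>"

# longest alternatives first: bracket atoms, two-char elements / ring closures /
# stereo marks, then any single character
_TOKEN_RE = re.compile(
    r"\[[^\]]*\]"
    r"|Cl|Br|Si|Se|Na|Ca|Li|Mg|Al|se|@@"
    r"|%\d{2}"
    r"|."
)


def split_smiles(smiles: str) -> list[str]:
    """Lex a SMILES string into surface tokens (no vocabulary involved)."""
    if not smiles:
        raise ValueError("empty SMILES string")
    return _TOKEN_RE.findall(smiles)


@dataclass(frozen=True)
class SmilesVocabulary:
    token_to_id: dict[str, int]

    def __post_init__(self) -> None:
        for i, special in enumerate((PAD_TOKEN, UNK_TOKEN, CLS_TOKEN)):
            if self.token_to_id.get(special) != i:
                raise ValueError(f"vocabulary must map {special!r} to id {i}")

    @classmethod
    def build(cls, corpus: Sequence[str]) -> "SmilesVocabulary":
        """Vocabulary over all surface tokens occurring in `corpus`, plus specials."""
        tokens = sorted({t for s in corpus for t in split_smiles(s)})
        mapping = {PAD_TOKEN: 0, UNK_TOKEN: 1, CLS_TOKEN: 2}
        for t in tokens:
            mapping[t] = len(mapping)
        return cls(mapping)

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    @property
    def cls_id(self) -> int:
        return 2

    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}


@dataclass(frozen=True)
class TokenizedDrug:
    token_ids: np.ndarray  # fixed max_len, pad-filled
    length: int            # attention length incl. the leading CLS token
    n_unknown: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "token_ids", np.asarray(self.token_ids, dtype=np.int64))


def tokenize_smiles(smiles: str, vocabulary: SmilesVocabulary, max_len: int = 128) -> TokenizedDrug:
    """CLS + greedy longest-match token ids, padded/truncated to `max_len`."""
    surface = split_smiles(smiles)
    ids = [vocabulary.cls_id] + [
        vocabulary.token_to_id.get(t, vocabulary.unk_id) for t in surface
    ]
    n_unknown = sum(1 for i in ids if i == vocabulary.unk_id)
    ids = ids[:max_len]
    length = len(ids)
    padded = np.full(max_len, vocabulary.pad_id, dtype=np.int64)
    padded[:length] = ids
    return TokenizedDrug(token_ids=padded, length=length, n_unknown=n_unknown)


def detokenize(tokenized: TokenizedDrug, vocabulary: SmilesVocabulary) -> str:
    """Concatenate non-special tokens; inverse of tokenize for in-vocabulary input."""
    lookup = vocabulary.id_to_token()
    specials = {vocabulary.pad_id, vocabulary.cls_id}
    return "".join(
        lookup[int(i)] for i in tokenized.token_ids[: tokenized.length] if int(i) not in specials
    )
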