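"""SMILES character vocabulary and one-hot sequence codec.

SMILES strings are treated as plain character sequences: ``Cl`` is the two
tokens ``C`` and ``l``, ``Br`` is ``B`` and ``r``.  Every sequence is framed
by a begin sentinel ``G`` and an end sentinel ``E``; both sentinels are part
of the vocabulary, so a corpus over the three elements C/N/O plus the two
sentinels has V = 5.  The sentinels are ordinary ASCII letters that never
occur as chemistry characters in valid SMILES, which is what makes the
single-character framing safe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BEGIN = "G"
END = "E"
SENTINELS = (BEGIN, END)


class CodecError(ValueError):
    """Raised for vocabulary construction and encoding failures."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token set with begin/end sentinels and a token<->index bijection.

    Tokens are the sorted chemistry characters of the corpus followed by the
    two sentinels, so indices are contiguous ``0..V-1`` and stable across
    rebuilds from the same corpus.
    """

    tokens: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, hash=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})
        if len(self.index) != len(self.tokens):
            raise CodecError("duplicate tokens in vocabulary")
        for s in SENTINELS:
            if s not in self.index:
                raise CodecError(f"sentinel {s!r} missing from vocabulary")
        if len(self.tokens) < 3:
            raise CodecError("vocabulary needs at least one chemistry token")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def begin_index(self) -> int:
        return self.index[BEGIN]

    @property
    def end_index(self) -> int:
        return self.index[END]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"tokens": list(self.tokens)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        data = json.loads(Path(path).read_text())
        return cls(tokens=tuple(data["tokens"]))


@dataclass(frozen=True)
class EncodedSequence:
    """One-hot matrix (L x V) of ``G`` + source characters + ``E``."""

    matrix: np.ndarray
    source: str

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Build the character vocabulary of a SMILES corpus.

    Tokens are the lexicographically sorted set of characters occurring in
    the corpus with the sentinels ``G`` and ``E`` appended last.  A corpus
    string containing a sentinel character is rejected: it would collide
    with the begin/end framing.
    """
    chars: set[str] = set()
    n = 0
    for s in corpus:
        n += 1
        if not s:
            raise CodecError("empty SMILES string in corpus")
        chars.update(s)
    if n == 0:
        raise CodecError("empty corpus")
    for s in SENTINELS:
        if s in chars:
            raise CodecError(
                f"corpus contains the sentinel character {s!r}; "
                "sentinel collision is not supported"
            )
    return Vocabulary(tokens=tuple(sorted(chars)) + SENTINELS)


def encode(smiles: str, vocab: Vocabulary) -> EncodedSequence:
    """One-hot encode a SMILES string with G/E framing (L = len(s) + 2)."""
    V = len(vocab)
    idx = np.empty(len(smiles) + 2, dtype=np.int64)
    idx[0] = vocab.begin_index
    for pos, ch in enumerate(smiles):
        j = vocab.index.get(ch)
        if j is None:
            raise CodecError(f"unknown character {ch!r} at position {pos}")
        idx[pos + 1] = j
    idx[-1] = vocab.end_index
    mat = np.zeros((len(idx), V), dtype=np.float32)
    mat[np.arange(len(idx)), idx] = 1.0
    return EncodedSequence(matrix=mat, source=smiles)


def encode_indices(smiles: str, vocab: Vocabulary) -> np.ndarray:
    """Integer-index form of :func:`encode` (G + chars + E)."""
    return np.asarray(encode(smiles, vocab).matrix.argmax(axis=1))


def decode(indices: Sequence[int], vocab: Vocabulary) -> str:
    """Map token indices back to a SMILES string.

    Sentinels are stripped; the sequence is truncated at the first ``E`` so
    generation-time tails after the stop token are discarded.
    """
    out: list[str] = []
    for i in indices:
        if not 0 <= int(i) < len(vocab):
            raise CodecError(f"token index {i} out of range (V={len(vocab)})")
        tok = vocab.tokens[int(i)]
        if tok == END:
            break
        if tok == BEGIN:
            continue
        out.append(tok)
    return "".join(out)


def read_smi(path: str | Path) -> list[str]:
    """Read a .smi file: one SMILES per line, optional tab-separated id,
    ``#`` comment lines and blank lines skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split("\t")[0].split()[0])
    return out


def write_smi(path: str | Path, smiles: Iterable[str]) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")
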