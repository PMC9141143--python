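"""Alphabets, instances, integer encoding and file I/O.

Candidate supersequences and input strings are stored as 1-D int64
arrays of symbol codes. An :class:`Alphabet` maps its ordered symbols
positionally onto the code range ``[0, |symbols| - 1]``; that range is
also the feasible region used by the opposition transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._kernels import greedy_match_counts, is_subseq

__all__ = [
    "Alphabet",
    "Instance",
    "DNA",
    "PROTEIN",
    "encode",
    "decode",
    "is_subsequence",
    "is_common_supersequence",
    "read_instance",
    "write_result",
]


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol set with positional integer codes.

    ``a`` and ``b`` are the inclusive code bounds: symbol i maps to code
    i, so a = 0 and b = len(symbols) - 1. Symbols are case-folded to
    lower case; encoding is case-insensitive.
    """

    symbols: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        syms = tuple(s.lower() for s in self.symbols)
        if not syms:
            raise ValueError("alphabet must contain at least one symbol")
        for s in syms:
            if len(s) != 1:
                raise ValueError(f"alphabet symbols must be single characters, got {s!r}")
        if len(set(syms)) != len(syms):
            raise ValueError("alphabet symbols must be distinct")
        object.__setattr__(self, "symbols", syms)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(syms)})

    @classmethod
    def from_string(cls, s: str) -> "Alphabet":
        return cls(tuple(s))

    @property
    def a(self) -> int:
        return 0

    @property
    def b(self) -> int:
        return len(self.symbols) - 1

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def code(self, char: str) -> int:
        try:
            return self._index[char.lower()]
        except KeyError:
            raise ValueError(f"character {char!r} is not in the alphabet") from None


#: Standard nucleotide alphabet (codes a=0, c=1, g=2, t=3).
DNA = Alphabet.from_string("acgt")
#: The twenty standard amino acids in lexicographic order.
PROTEIN = Alphabet.from_string("acdefghiklmnpqrstvwy")


def encode(text: str, alphabet: Alphabet) -> np.ndarray:
    """Encode ``text`` as the int64 array of positional codes.

    Raises ``ValueError`` naming the offending character and position if
    any character is outside the alphabet.
    """
    codes = np.empty(len(text), dtype=np.int64)
    index = alphabet._index
    for i, ch in enumerate(text):
        c = index.get(ch.lower())
        if c is None:
            raise ValueError(f"character {ch!r} at position {i} is not in the alphabet")
        codes[i] = c
    return codes


def decode(x, alphabet: Alphabet) -> str:
    """Inverse of :func:`encode`; rejects out-of-range codes."""
    x = np.asarray(x, dtype=np.int64)
    if x.size and (x.min() < alphabet.a or x.max() > alphabet.b):
        raise ValueError("code outside the alphabet range")
    syms = alphabet.symbols
    return "".join(syms[c] for c in x)


class Instance:
    """A set of encoded input strings sharing one alphabet.

    Rows are zero-padded into a matrix (``padded``, ``lengths``) for the
    compiled scanning kernels; the padding is never read.
    """

    def __init__(self, strings, alphabet: Alphabet, name: str = ""):
        strings = [np.asarray(s, dtype=np.int64) for s in strings]
        if not strings:
            raise ValueError("an instance needs at least one string")
        for s in strings:
            if s.size == 0:
                raise ValueError("input strings must be non-empty")
            if s.min() < alphabet.a or s.max() > alphabet.b:
                raise ValueError("string code outside the alphabet range")
        self.strings = strings
        self.alphabet = alphabet
        self.name = name
        self.lengths = np.array([s.size for s in strings], dtype=np.int64)
        self.padded = np.zeros((len(strings), int(self.lengths.max())), dtype=np.int64)
        for j, s in enumerate(strings):
            self.padded[j, : s.size] = s

    @property
    def n(self) -> int:
        return len(self.strings)

    @property
    def total_chars(self) -> int:
        return int(self.lengths.sum())

    @property
    def max_length(self) -> int:
        return int(self.lengths.max())

    def __repr__(self):
        return f"Instance(name={self.name!r}, n={self.n}, lengths={self.lengths.tolist()})"

    @classmethod
    def from_texts(cls, texts, alphabet: Alphabet, name: str = "") -> "Instance":
        return cls([encode(t, alphabet) for t in texts], alphabet, name=name)


def is_subsequence(s, t) -> bool:
    """True iff ``s`` is obtainable from ``t`` by deleting elements
    (greedy left-to-right scan)."""
    s = np.asarray(s, dtype=np.int64)
    t = np.asarray(t, dtype=np.int64)
    return bool(is_subseq(s, t))


def is_common_supersequence(cand, inst: Instance) -> bool:
    """True iff every instance string is a subsequence of ``cand``."""
    cand = np.asarray(cand, dtype=np.int64)
    matched = greedy_match_counts(cand, inst.padded, inst.lengths)
    return bool(np.all(matched == inst.lengths))


def read_instance(path, format: str = "lines", alphabet=None, name: str | None = None) -> Instance:
    """Read an instance from a FASTA file (one string per record) or a
    plain text file (one string per line).

    With ``alphabet=None`` (or the string ``"infer"``) the alphabet is
    the sorted set of characters seen in the file.
    """
    path = Path(path)
    if format == "fasta":
        texts = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    elif format == "lines":
        texts = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    else:
        raise ValueError(f"unknown format {format!r}")
    if not texts:
        raise ValueError(f"no sequences found in {path}")
    if alphabet is None or alphabet == "infer":
        alphabet = Alphabet(tuple(sorted({ch.lower() for t in texts for ch in t})))
    return Instance.from_texts(texts, alphabet, name=name if name is not None else path.stem)


def write_result(path, best, inst: Instance, stats: dict) -> None:
    """Write a result report: TSV at ``path`` plus a JSON mirror at
    ``path + '.json'``. Refuses to write an invalid supersequence."""
    best = np.asarray(best, dtype=np.int64)
    if not is_common_supersequence(best, inst):
        raise ValueError("refusing to write: candidate is not a common supersequence")
    path = Path(path)
    k = int(inst.lengths.max())
    record = {
        "instance": inst.name,
        "n": inst.n,
        "k": k,
        "algo": stats.get("algo", ""),
        "seed": stats.get("seed"),
        "length": int(best.size),
        "iterations": stats.get("iterations"),
        "supersequence": decode(best, inst.alphabet),
    }
    cols = ["instance", "n", "k", "algo", "seed", "length", "iterations", "supersequence"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(str(record[c]) for c in cols) + "\n")
    extra = {k_: v for k_, v in stats.items() if k_ not in record}
    with open(str(path) + ".json", "w") as fh:
        json.dump({**record, **extra}, fh, indent=2)
        fh.write("\n")
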