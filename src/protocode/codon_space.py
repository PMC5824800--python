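"""The 64 codons: numeric encoding, mutational neighbourhoods, codon tables.

Bases are ordered U < C < A < G; codons are indexed 0..63 in lexicographic
order over that alphabet (UUU, UUC, UUA, UUG, UCU, ...). The numeric input
encoding places pyrimidines and purines unevenly on the unit interval:
U=0.0, C=0.3, A=0.7, G=1.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np

__all__ = [
    "BASES",
    "BASE_ENCODING",
    "CODONS",
    "codon_index",
    "encode_codon",
    "CODON_ENCODINGS",
    "single_nucleotide_neighbors",
    "NEIGHBOR_INDICES",
    "CodonTable",
    "table_distance",
]

BASES = ("U", "C", "A", "G")
BASE_ENCODING = {"U": 0.0, "C": 0.3, "A": 0.7, "G": 1.0}

#: All 64 codons in canonical (lexicographic over U,C,A,G) order.
CODONS: tuple[str, ...] = tuple(
    b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES
)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


def codon_index(codon: str) -> int:
    """Canonical 0..63 index of a codon string."""
    try:
        return _CODON_INDEX[codon]
    except KeyError:
        raise ValueError(f"invalid codon: {codon!r}") from None


def encode_codon(codon: str) -> np.ndarray:
    """Map a codon to its 3-vector input encoding (U=0, C=0.3, A=0.7, G=1)."""
    if len(codon) != 3:
        raise ValueError(f"invalid codon: {codon!r}")
    try:
        return np.array([BASE_ENCODING[b] for b in codon])
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in codon {codon!r}") from None


#: Precomputed (64, 3) matrix of codon input encodings, canonical order.
CODON_ENCODINGS: np.ndarray = np.stack([encode_codon(c) for c in CODONS])
CODON_ENCODINGS.setflags(write=False)


def single_nucleotide_neighbors(codon: str) -> set[str]:
    """The 9 codons differing from ``codon`` at exactly one position."""
    if codon not in _CODON_INDEX:
        raise ValueError(f"invalid codon: {codon!r}")
    out = set()
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                out.add(codon[:pos] + b + codon[pos + 1 :])
    return out


def _neighbor_indices() -> np.ndarray:
    nbr = np.empty((64, 9), dtype=np.int64)
    for i, c in enumerate(CODONS):
        nbr[i] = sorted(_CODON_INDEX[n] for n in single_nucleotide_neighbors(c))
    return nbr


#: (64, 9) array: row i holds the canonical indices of codon i's neighbours.
NEIGHBOR_INDICES: np.ndarray = _neighbor_indices()
NEIGHBOR_INDICES.setflags(write=False)


@dataclass(frozen=True)
class CodonTable:
    """A total assignment of the 64 codons to amino-acid identities.

    ``assignments`` is an int64 array of length 64 giving, for the codon
    with canonical index i, the canonical amino-acid index (0..19) of its
    assigned amino acid. ``names`` maps those indices to three-letter
    codes for serialization.
    """

    assignments: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignments, dtype=np.int64)
        if arr.shape != (64,):
            raise ValueError("a codon table must assign all 64 codons")
        if arr.min() < 0 or arr.max() >= len(self.names):
            raise ValueError("assignment index out of range")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "assignments", arr)
        object.__setattr__(self, "names", tuple(self.names))

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, str], names: Iterable[str]
    ) -> "CodonTable":
        names = tuple(names)
        idx = {n: i for i, n in enumerate(names)}
        missing = [c for c in CODONS if c not in mapping]
        if missing:
            raise ValueError(f"codon table is not total; missing {missing[:3]}...")
        arr = np.array([idx[mapping[c]] for c in CODONS], dtype=np.int64)
        return cls(arr, names)

    def __getitem__(self, codon: str) -> str:
        return self.names[self.assignments[codon_index(codon)]]

    def to_mapping(self) -> dict[str, str]:
        return {c: self.names[a] for c, a in zip(CODONS, self.assignments)}

    def amino_acid_counts(self) -> np.ndarray:
        """Codons assigned per amino-acid index; sums to 64."""
        return np.bincount(self.assignments, minlength=len(self.names))

    # ------------------------------------------------------------------
    # serialization: two-column TSV and JSON-with-metadata
    # ------------------------------------------------------------------

    def write_tsv(self, path: str | Path | IO[str]) -> None:
        lines = ["codon\tamino_acid\n"] + [
            f"{c}\t{self.names[a]}\n" for c, a in zip(CODONS, self.assignments)
        ]
        if hasattr(path, "write"):
            path.writelines(lines)
        else:
            Path(path).write_text("".join(lines))

    @classmethod
    def read_tsv(cls, path: str | Path | IO[str]) -> "CodonTable":
        if hasattr(path, "read"):
            text = path.read()
            label = "<stream>"
        else:
            text = Path(path).read_text()
            label = str(path)
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0].split("\t")[:2] != ["codon", "amino_acid"]:
            raise ValueError(f"{label}:1: expected header 'codon\\tamino_acid'")
        mapping: dict[str, str] = {}
        for lineno, ln in enumerate(lines[1:], start=2):
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{label}:{lineno}: expected 2 columns")
            codon, aa = parts
            if codon not in _CODON_INDEX:
                raise ValueError(f"{label}:{lineno}: invalid codon {codon!r}")
            if codon in mapping:
                raise ValueError(f"{label}:{lineno}: duplicate codon {codon!r}")
            mapping[codon] = aa
        names = tuple(sorted(set(mapping.values())))
        return cls.from_mapping(mapping, names)

    def to_json(self, **metadata) -> str:
        return json.dumps(
            {"metadata": metadata, "assignments": self.to_mapping()}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> tuple["CodonTable", dict]:
        obj = json.loads(text)
        mapping = obj["assignments"]
        names = tuple(sorted(set(mapping.values())))
        return cls.from_mapping(mapping, names), obj.get("metadata", {})


def table_distance(a: CodonTable, b: CodonTable) -> int:
    """Number of codons assigned to different amino acids in ``a`` vs ``b``.

    A Hamming distance on tables, in [0, 64]; compares amino-acid names so
    tables need not share an index ordering.
    """
    if a.names == b.names:
        return int(np.count_nonzero(a.assignments != b.assignments))
    an, bn = a.names, b.names
    return sum(
        an[x] != bn[y] for x, y in zip(a.assignments, b.assignments)
    )
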