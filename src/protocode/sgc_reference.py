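"""The standard genetic code as a fixed comparator.

The canonical 64-codon table: 61 sense codons covering all 20 amino acids
plus the three stop codons (UAA, UAG, UGA). Stops carry no amino-acid
identity and are invisible to the simulator; they matter only when scoring
the standard code itself, where they are excluded from the robustness
measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np

from .codon_space import CODONS, CodonTable

__all__ = ["STOP_LABEL", "StandardCode", "sgc_table"]

STOP_LABEL = "Stop"

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

# 64 one-letter assignments in canonical codon order (U, C, A, G nested
# first->third position); '*' marks a stop codon.
_SGC_STRING = (
    "FFLL" "SSSS" "YY**" "CC*W"  # UNN
    "LLLL" "PPPP" "HHQQ" "RRRR"  # CNN
    "IIIM" "TTTT" "NNKK" "SSRR"  # ANN
    "VVVV" "AAAA" "DDEE" "GGGG"  # GNN
)


@dataclass(frozen=True)
class StandardCode:
    """The universal codon table, with stop codons marked explicitly."""

    mapping: dict  # codon -> three-letter code or STOP_LABEL

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.mapping[c] == STOP_LABEL)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.mapping[c] != STOP_LABEL)

    def sense_mask(self) -> np.ndarray:
        """Boolean length-64 mask of sense codons in canonical order."""
        return np.array([self.mapping[c] != STOP_LABEL for c in CODONS])

    def to_codon_table(self) -> CodonTable:
        """As a plain ``CodonTable`` (stops keep the ``Stop`` label)."""
        names = tuple(sorted(set(self.mapping.values())))
        return CodonTable.from_mapping(self.mapping, names)

    def write_tsv(self, path: str | Path | IO[str]) -> None:
        self.to_codon_table().write_tsv(path)


def sgc_table() -> StandardCode:
    """The canonical standard genetic code; stable across calls."""
    mapping = {}
    for codon, one in zip(CODONS, _SGC_STRING):
        mapping[codon] = STOP_LABEL if one == "*" else _ONE_TO_THREE[one]
    return StandardCode(mapping)
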