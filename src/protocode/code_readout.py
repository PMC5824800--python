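"""Reading the genetic code out of a network, and the obverter codon choice.

``read_code`` decodes all 64 codons through a network and assigns each to
the nearest amino acid in chemical space. ``obverter_codon`` is the
production-side inverse: to transmit an amino acid, pick the codon whose
decoded output lands closest to that amino acid's chemical vector.
"""

from __future__ import annotations

import numpy as np

from .chemical_space import AminoAcidDescriptor, AminoAcidTable
from .codon_space import CODONS, CODON_ENCODINGS, CodonTable
from .translation_network import PerceptronTranslator, forward_batch

__all__ = [
    "decode_assignments",
    "read_code",
    "expressivity",
    "obverter_codon",
    "obverter_codon_index",
]


def decode_assignments(
    net: PerceptronTranslator, aa_table: AminoAcidTable
) -> np.ndarray:
    """Per-codon nearest-amino-acid indices (length-64 int array)."""
    out = forward_batch(net, CODON_ENCODINGS)  # (64, 11)
    d2 = ((out[:, None, :] - aa_table.chem_matrix[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # first minimum = canonical tie-break


def read_code(net: PerceptronTranslator, aa_table: AminoAcidTable) -> CodonTable:
    """The total codon table implied by a network's decoding behaviour."""
    return CodonTable(decode_assignments(net, aa_table), aa_table.names3)


def expressivity(table: CodonTable) -> int:
    """Number of distinct amino acids among the 64 assignments (1..20)."""
    return int(len(np.unique(table.assignments)))


def obverter_codon_index(
    net: PerceptronTranslator, target: AminoAcidDescriptor
) -> int:
    """Canonical index of the codon whose output best matches ``target``.

    Exhaustive scan over all 64 codons; ties resolve to the lowest
    canonical codon index.
    """
    out = forward_batch(net, CODON_ENCODINGS)
    d2 = ((out - target.chem_vector) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def obverter_codon(net: PerceptronTranslator, target: AminoAcidDescriptor) -> str:
    """The codon this network would itself decode closest to ``target``."""
    return CODONS[obverter_codon_index(net, target)]
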