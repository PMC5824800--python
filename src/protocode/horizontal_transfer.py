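"""One communal-evolution event: fragment sampling and assimilation.

A donor protocell emits 10 signal-meaning pairs — codons chosen by its own
obverter readout, paired with target amino acids drawn by abundance-biased
sampling without replacement from all 20 amino acids. The receiver
assimilates the fragment by backpropagation training (500 presentations of
each pair by default). Transmission errors are emergent: the donor's
obverter codon may decode, under the donor's own table, to a different
amino acid nearby in chemical space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemical_space import AminoAcidDescriptor, AminoAcidTable
from .codon_space import CODONS, CODON_ENCODINGS, codon_index, encode_codon
from .code_readout import decode_assignments
from .translation_network import PerceptronTranslator, forward_batch, train_on_pairs

__all__ = [
    "TransferRecord",
    "sample_amino_acid_indices",
    "sample_fragment",
    "fragment_disagreements",
    "apply_transfer",
]


@dataclass
class TransferRecord:
    """Log entry for a single horizontal transfer."""

    donor: int
    receiver: int
    pairs: list  # [(codon, three-letter amino acid), ...]
    disagreements: int  # pairs whose codon decodes differently in the donor
    receiver_expressivity: int
    receiver_delta_code: float

    def to_json_line(self) -> str:
        return json.dumps(
            {
                "donor": self.donor,
                "receiver": self.receiver,
                "pairs": [[c, a] for c, a in self.pairs],
                "disagreements": self.disagreements,
                "receiver_expressivity": self.receiver_expressivity,
                "receiver_delta_code": self.receiver_delta_code,
            }
        )


def sample_amino_acid_indices(
    weights: np.ndarray, rng: np.random.Generator, n: int = 10
) -> np.ndarray:
    """Draw ``n`` distinct indices, successively, proportional to weight.

    After each draw the chosen index is removed and the remaining weights
    renormalized (weighted sampling without replacement).
    """
    w = np.asarray(weights, dtype=float).copy()
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("transfer weights must be finite and non-negative")
    if np.count_nonzero(w > 0) < n:
        raise ValueError(f"need at least {n} amino acids with positive weight")
    out = np.empty(n, dtype=np.int64)
    for k in range(n):
        c = np.cumsum(w)
        u = rng.random() * c[-1]
        i = int(np.searchsorted(c, u, side="right"))
        i = min(i, len(w) - 1)  # guard against u == total mass
        out[k] = i
        w[i] = 0.0
    return out


def sample_fragment(
    donor_net: PerceptronTranslator,
    aa_table: AminoAcidTable,
    rng: np.random.Generator,
    n_pairs: int = 10,
) -> list[tuple[str, AminoAcidDescriptor]]:
    """Sample a code fragment of ``n_pairs`` (codon, amino acid) pairs.

    Amino acids are drawn without replacement with probability
    proportional to their transfer weight; each is paired with the donor's
    obverter codon for it.
    """
    aa_idx = sample_amino_acid_indices(aa_table.transfer_weights, rng, n_pairs)
    out = forward_batch(donor_net, CODON_ENCODINGS)  # (64, 11)
    d2 = ((out[:, None, :] - aa_table.chem_matrix[None, :, :]) ** 2).sum(axis=2)
    codons = np.argmin(d2[:, aa_idx], axis=0)
    return [(CODONS[c], aa_table[int(k)]) for c, k in zip(codons, aa_idx)]


def fragment_disagreements(
    fragment: Sequence[tuple[str, AminoAcidDescriptor]],
    donor_net: PerceptronTranslator,
    aa_table: AminoAcidTable,
) -> int:
    """How many transmitted pairs conflict with the donor's own read-out."""
    donor_assign = decode_assignments(donor_net, aa_table)
    return sum(
        1
        for codon, aa in fragment
        if donor_assign[codon_index(codon)] != aa_table.index(aa.name3)
    )


def apply_transfer(
    receiver_net: PerceptronTranslator,
    fragment: Sequence[tuple[str, AminoAcidDescriptor]],
    rng: np.random.Generator,
    epochs: int = 500,
) -> PerceptronTranslator:
    """Assimilate a fragment into the receiver by backprop training.

    Each (codon, amino acid) pair becomes a (codon encoding, chemical
    vector) training sample; pairs are presented one at a time in a fresh
    random order, ``epochs`` times. Updates the receiver in place.
    """
    pairs = [(encode_codon(c), aa.chem_vector) for c, aa in fragment]
    return train_on_pairs(receiver_net, pairs, epochs, rng)
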