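"""Amino acids as points in an 11-dimensional chemical property space.

Each of the 20 encoded amino acids is described by four continuous
properties (van der Waals volume, side-chain/alpha pKa, logP
hydrophobicity, molecular weight), five binary side-chain element flags
(C, N, O, S, benzene ring) and two binary backbone-type flags (Ia, IVa).
Continuous properties are min-max normalized to [0, 1] over the 20 amino
acids, so every amino acid is a distinct point in the unit 11-cube.

Auxiliary scalars carried alongside the vector: Woese polar requirement
(used by the code-optimality measure), raw molecular weight in daltons,
a coarse structural class (simple / complex / sulfur), aminoacyl-tRNA
synthetase class (I / II) and a positive transfer weight proportional to
cellular relative amino-acid abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AminoAcidDescriptor",
    "AminoAcidTable",
    "load_amino_acid_table",
    "nearest_amino_acid",
    "nearest_amino_acid_index",
    "CHEM_DIMS",
]

#: Number of chemical-space dimensions.
CHEM_DIMS = 11

_CONTINUOUS_COLS = ("vdw_volume", "pka", "logp", "mol_weight")
_BINARY_COLS = ("sc_c", "sc_n", "sc_o", "sc_s", "sc_benzene", "bb_ia", "bb_iva")
_REQUIRED_COLS = (
    "name3",
    "name1",
    *_CONTINUOUS_COLS,
    *_BINARY_COLS,
    "polar_requirement",
    "aa_class",
    "aars_class",
    "transfer_weight",
)
_VALID_CLASSES = frozenset({"simple", "complex", "sulfur"})
_VALID_AARS = frozenset({"I", "II"})


@dataclass(frozen=True)
class AminoAcidDescriptor:
    """One encoded amino acid and its chemical-space coordinates."""

    name3: str
    name1: str
    chem_vector: np.ndarray  # shape (11,), continuous dims in [0,1], flags 0/1
    polar_requirement: float
    molecular_weight_raw: float
    aa_class: str
    aars_class: str
    transfer_weight: float

    def __post_init__(self) -> None:
        vec = np.asarray(self.chem_vector, dtype=float)
        if vec.shape != (CHEM_DIMS,):
            raise ValueError(
                f"{self.name3}: chem_vector must have {CHEM_DIMS} components"
            )
        object.__setattr__(self, "chem_vector", vec)


class AminoAcidTable:
    """Immutable collection of the 20 amino-acid descriptors.

    Descriptors are kept in canonical order (alphabetical three-letter
    code); that order defines the integer index used throughout the
    simulator and breaks nearest-neighbour ties deterministically.
    """

    def __init__(self, descriptors: Sequence[AminoAcidDescriptor]):
        self.descriptors = tuple(
            sorted(descriptors, key=lambda d: d.name3)
        )
        self.names3 = tuple(d.name3 for d in self.descriptors)
        self.names1 = tuple(d.name1 for d in self.descriptors)
        self.chem_matrix = (
            np.stack([d.chem_vector for d in self.descriptors])
            if self.descriptors
            else np.zeros((0, CHEM_DIMS))
        )
        self.chem_matrix.setflags(write=False)
        self.polar_requirement = np.array(
            [d.polar_requirement for d in self.descriptors]
        )
        self.molecular_weight_raw = np.array(
            [d.molecular_weight_raw for d in self.descriptors]
        )
        self.transfer_weights = np.array(
            [d.transfer_weight for d in self.descriptors]
        )
        self.aa_classes = tuple(d.aa_class for d in self.descriptors)
        self.aars_classes = tuple(d.aars_class for d in self.descriptors)
        self._index = {n: i for i, n in enumerate(self.names3)}

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self) -> Iterator[AminoAcidDescriptor]:
        return iter(self.descriptors)

    def __getitem__(self, key: int | str) -> AminoAcidDescriptor:
        if isinstance(key, str):
            key = self._index[key]
        return self.descriptors[key]

    def index(self, name3: str) -> int:
        """Canonical integer index of a three-letter amino-acid code."""
        return self._index[name3]


def _validate_rows(df: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"amino-acid table missing columns: {missing}")
    if len(df) != 20:
        raise ValueError(f"amino-acid table must have 20 rows, got {len(df)}")
    dup = df["name3"][df["name3"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate amino-acid name: {dup.iloc[0]!r}")
    for col in _BINARY_COLS:
        bad = df.loc[~df[col].isin([0, 1]), "name3"]
        if not bad.empty:
            raise ValueError(
                f"non-binary value in column {col!r} for row {bad.iloc[0]!r}"
            )
    for col in (*_CONTINUOUS_COLS, "polar_requirement", "transfer_weight"):
        bad = df.loc[~np.isfinite(df[col].astype(float)), "name3"]
        if not bad.empty:
            raise ValueError(f"non-finite {col!r} for row {bad.iloc[0]!r}")
    bad = df.loc[df["transfer_weight"].astype(float) <= 0, "name3"]
    if not bad.empty:
        raise ValueError(f"non-positive transfer_weight for row {bad.iloc[0]!r}")
    bad = df.loc[~df["aa_class"].isin(_VALID_CLASSES), "name3"]
    if not bad.empty:
        raise ValueError(f"unknown aa_class for row {bad.iloc[0]!r}")
    bad = df.loc[~df["aars_class"].isin(_VALID_AARS), "name3"]
    if not bad.empty:
        raise ValueError(f"unknown aars_class for row {bad.iloc[0]!r}")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant property")
    return (values - lo) / (hi - lo)


def load_amino_acid_table(
    source: str | Path | IO[str] | None = None,
) -> AminoAcidTable:
    """Load the 20 amino-acid descriptors from a TSV file.

    With ``source=None`` the packaged default property table is used.
    Continuous properties are min-max normalized over the 20 rows, which
    maps the extreme raw values to exactly 0 and 1.

    Raises ``ValueError`` for tables that do not describe exactly 20
    uniquely named amino acids with binary flags and positive weights.
    """
    if source is None:
        ref = resources.files("protocode.data").joinpath("amino_acids.tsv")
        with ref.open("r") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(source, sep="\t")
    _validate_rows(df)

    norm = {c: _minmax(df[c].to_numpy(dtype=float)) for c in _CONTINUOUS_COLS}
    descriptors = []
    for i, row in df.iterrows():
        vec = np.array(
            [norm[c][i] for c in _CONTINUOUS_COLS]
            + [float(row[c]) for c in _BINARY_COLS]
        )
        descriptors.append(
            AminoAcidDescriptor(
                name3=str(row["name3"]),
                name1=str(row["name1"]),
                chem_vector=vec,
                polar_requirement=float(row["polar_requirement"]),
                molecular_weight_raw=float(row["mol_weight"]),
                aa_class=str(row["aa_class"]),
                aars_class=str(row["aars_class"]),
                transfer_weight=float(row["transfer_weight"]),
            )
        )
    table = AminoAcidTable(descriptors)
    vecs = table.chem_matrix
    if len(np.unique(vecs, axis=0)) != 20:
        raise ValueError("amino-acid chemical vectors are not pairwise distinct")
    return table


def nearest_amino_acid_index(point: np.ndarray, table: AminoAcidTable) -> int:
    """Index of the amino acid closest (Euclidean) to ``point`` in 11-space.

    Ties resolve to the lowest canonical index (alphabetical order).
    """
    point = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(point)):
        raise ValueError("point components must be finite")
    if len(table) == 0:
        raise ValueError("empty amino-acid table")
    d2 = np.sum((table.chem_matrix - point) ** 2, axis=1)
    return int(np.argmin(d2))  # argmin returns the first minimum


def nearest_amino_acid(
    point: np.ndarray, table: AminoAcidTable
) -> AminoAcidDescriptor:
    """The amino acid whose chemical vector is nearest to ``point``."""
    return table[nearest_amino_acid_index(point, table)]
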