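"""Code-quality measures: single-nucleotide error robustness and universality.

``delta_code`` scores a codon table's robustness to point mutations: for
each codon, average the squared polar-requirement difference between its
amino acid and those of its nine single-nucleotide neighbours, then
average over codons. Lower is more robust. A codon subset restricts both
the codons iterated over and, by default, the neighbours counted — the
configuration that reproduces the standard code's published baseline.

``universality`` summarizes how similar a population of codes is: the mean
(and standard deviation) of the pairwise table distance.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .chemical_space import AminoAcidTable
from .codon_space import NEIGHBOR_INDICES, CodonTable, codon_index, table_distance

__all__ = ["delta_code", "delta_code_from_assignments", "universality"]


def delta_code_from_assignments(
    assignments: np.ndarray,
    polar_requirement: np.ndarray,
    include: np.ndarray | None = None,
    neighbor_handling: str = "exclude",
    average: str = "squared",
) -> float:
    """`delta_code` on raw index arrays (fast path used by the simulator).

    ``assignments`` maps codon index -> amino-acid index; entries for
    codons outside ``include`` are ignored. ``neighbor_handling``:
    'exclude' drops excluded neighbours from a codon's average,
    'count_all' keeps the divisor at 9. ``average``: 'squared' uses the
    mean squared difference per codon, 'rms' its square root.
    """
    if neighbor_handling not in ("exclude", "count_all"):
        raise ValueError(f"unknown neighbor_handling {neighbor_handling!r}")
    if average not in ("squared", "rms"):
        raise ValueError(f"unknown average {average!r}")
    if include is None:
        include = np.ones(64, dtype=bool)
    else:
        include = np.asarray(include, dtype=bool)
        if include.shape != (64,):
            raise ValueError("include mask must have length 64")
    if not include.any():
        raise ValueError("codon subset is empty")

    pr = np.where(include, polar_requirement[assignments], 0.0)
    nbr_ok = include[NEIGHBOR_INDICES]  # (64, 9)
    sq = (pr[:, None] - pr[NEIGHBOR_INDICES]) ** 2
    sq = np.where(nbr_ok, sq, 0.0)
    counts = nbr_ok.sum(axis=1)
    denom = np.where(neighbor_handling == "exclude", counts, 9)
    # codons with no counted neighbour cannot contribute an average
    valid = include & (counts > 0)
    if not valid.any():
        raise ValueError("no codon in the subset has a neighbour in the subset")
    per_codon = sq.sum(axis=1)[valid] / denom[valid]
    if average == "rms":
        per_codon = np.sqrt(per_codon)
    return float(per_codon.mean())


def delta_code(
    table: CodonTable,
    aa_table: AminoAcidTable,
    codon_subset: Iterable[str] | None = None,
    neighbor_handling: str = "exclude",
    average: str = "squared",
) -> float:
    """Mean per-codon squared polar-requirement change under point mutation."""
    # names absent from the amino-acid table (e.g. stop labels) are legal
    # only outside the codon subset, where their value is never read
    known = {n: aa_table.index(n) for n in table.names if n in aa_table.names3}
    aa_idx = np.array([known.get(n, 0) for n in table.names])
    assignments = aa_idx[table.assignments]
    include = None
    if codon_subset is not None:
        include = np.zeros(64, dtype=bool)
        for c in codon_subset:
            include[codon_index(c)] = True
    inside = np.ones(64, dtype=bool) if include is None else include
    for ci in np.nonzero(inside)[0]:
        name = table.names[table.assignments[ci]]
        if name not in known:
            raise ValueError(f"codon subset includes unknown amino acid {name!r}")
    return delta_code_from_assignments(
        assignments,
        aa_table.polar_requirement,
        include=include,
        neighbor_handling=neighbor_handling,
        average=average,
    )


def universality(codes: Sequence[CodonTable]) -> tuple[float, float]:
    """Mean and standard deviation of pairwise table distance (0..64)."""
    if len(codes) < 2:
        raise ValueError("universality needs at least 2 codon tables")
    d = [table_distance(a, b) for a, b in combinations(codes, 2)]
    d = np.asarray(d, dtype=float)
    return float(d.mean()), float(d.std())
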