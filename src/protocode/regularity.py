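"""Post-hoc regularity analyses of evolved codes.

Given the most robust code from each independent run, these analyses ask
whether codon assignments favour structurally simple amino acids (raw and
class-size-corrected counts) and how per-amino-acid assignment counts
correlate with transfer probability and with molecular weight.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .chemical_space import AminoAcidTable
from .codon_space import CodonTable
from .code_readout import expressivity
from .metrics import delta_code

__all__ = [
    "select_optimal_codes",
    "assignments_per_class",
    "mean_assignment_counts",
    "assignment_correlations",
    "CorrelationResult",
]


def select_optimal_codes(
    run_populations: Sequence[Sequence[CodonTable]], aa_table: AminoAcidTable
) -> list[CodonTable]:
    """Most robust final code of each run.

    Minimal delta_code; ties broken by higher expressivity, then by the
    first protocell index.
    """
    chosen = []
    for codes in run_populations:
        if not codes:
            raise ValueError("a run supplied an empty population")
        key = [
            (delta_code(c, aa_table), -expressivity(c), i)
            for i, c in enumerate(codes)
        ]
        chosen.append(codes[min(range(len(codes)), key=key.__getitem__)])
    return chosen


def mean_assignment_counts(
    codes: Sequence[CodonTable], aa_table: AminoAcidTable
) -> np.ndarray:
    """Mean codons assigned to each of the 20 amino acids across codes."""
    if not codes:
        raise ValueError("no codes supplied")
    counts = np.zeros(len(aa_table))
    for code in codes:
        idx = np.array([aa_table.index(n) for n in code.names])
        counts += np.bincount(idx[code.assignments], minlength=len(aa_table))
    return counts / len(codes)


def assignments_per_class(
    codes: Sequence[CodonTable],
    aa_table: AminoAcidTable,
    corrected: bool = False,
) -> dict[str, float]:
    """Mean codon assignments per structural class across codes.

    Raw: total codons assigned to each class (sums to 64 over classes).
    Corrected: class totals divided by the number of amino acids in the
    class, removing the effect of unequal class sizes.
    """
    mean_counts = mean_assignment_counts(codes, aa_table)
    classes = np.array(aa_table.aa_classes)
    out: dict[str, float] = {}
    for cls in ("simple", "complex", "sulfur"):
        members = classes == cls
        total = float(mean_counts[members].sum())
        out[cls] = total / int(members.sum()) if corrected else total
    return out


class CorrelationResult(NamedTuple):
    vs_transfer_weight: float
    vs_molecular_weight: float


def assignment_correlations(
    codes: Sequence[CodonTable],
    aa_table: AminoAcidTable,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlation of mean assignment counts with abundance and with mass.

    Returns NaN components (not an exception) when a variable has zero
    variance. ``method`` is 'spearman' (default) or 'pearson'.
    """
    if method == "spearman":
        corr = lambda a, b: stats.spearmanr(a, b).statistic
    elif method == "pearson":
        corr = lambda a, b: stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    counts = mean_assignment_counts(codes, aa_table)

    def safe(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(corr(a, b))

    return CorrelationResult(
        vs_transfer_weight=safe(counts, aa_table.transfer_weights),
        vs_molecular_weight=safe(counts, aa_table.molecular_weight_raw),
    )
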