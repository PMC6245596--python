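"""Statistical comparison of reaction-frequency tables from two experiments.

Two extraction runs are compared through their per-reaction occurrence
frequencies ``F`` and ``F'``: a paired Wilcoxon signed-rank test asks whether
the two frequency profiles could come from the same distribution (a standard
chi-square test is not applicable because stoichiometric coupling makes the
per-reaction frequencies dependent), and a chi-square-style divergence

    chi_bar = sum_i (F'_i - F_i)**2 / F_i      (over F_i > 0)

quantifies the size of the shift.  chi_bar is reported as a bare statistic:
no reference distribution is claimed for it, so it orders experiments by
dissimilarity without attaching a significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = [
    "FrequencyTable",
    "ComparisonResult",
    "wilcoxon_signed_rank",
    "chi_bar_squared",
    "compare",
    "write_comparison_tsv",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Per-reaction occurrence counts of one extraction experiment."""

    reaction_ids: tuple[str, ...]
    O: np.ndarray
    N: int
    p: float = float("nan")

    def __post_init__(self) -> None:
        O = np.asarray(self.O, dtype=np.int64)
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "O", O)
        if O.shape != (len(self.reaction_ids),):
            raise ValueError("occurrence vector must align with reaction_ids")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if np.any(O < 0) or np.any(O > self.N):
            raise ValueError("occurrences must lie in 0..N")

    @property
    def F(self) -> np.ndarray:
        return self.O / self.N


@dataclass(frozen=True)
class ComparisonResult:
    """Wilcoxon p-value and chi-bar statistic for a pair of frequency tables."""

    wilcoxon_p: float
    chi_bar: float
    pairs_used_wilcoxon: int
    pairs_used_chibar: int
    N_a: int
    N_b: int
    p_a: float
    p_b: float


def wilcoxon_signed_rank(F: Sequence[float], Fprime: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on ``F' - F``.

    Zero differences are dropped (Wilcoxon's original exclusion rule); the
    exact null distribution (enumeration over the 2^n sign assignments) is
    used for up to 25 nonzero pairs, the normal approximation with tie
    correction otherwise.  When every difference is zero the profiles are
    indistinguishable and 1.0 is returned.
    """
    F = np.asarray(F, dtype=float)
    Fprime = np.asarray(Fprime, dtype=float)
    if F.shape != Fprime.shape:
        raise ValueError(f"length mismatch: {F.shape} vs {Fprime.shape}")
    d = Fprime - F
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    with warnings.catch_warnings():
        # with tied |d| scipy warns that the exact tail is uncorrected; fine here
        warnings.simplefilter("ignore")
        res = scipy.stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)


def chi_bar_squared(F: Sequence[float], Fprime: Sequence[float]) -> float:
    """Chi-square-style divergence of ``F'`` from the reference ``F``.

    Terms with ``F_i = 0`` are skipped (the reference frequency is the
    denominator), so the statistic is not symmetric in its arguments.  Use
    :func:`compare` to also learn how many pairs were skipped.
    """
    stat, _ = _chi_bar(F, Fprime)
    return stat


def _chi_bar(F: Sequence[float], Fprime: Sequence[float]) -> tuple[float, int]:
    F = np.asarray(F, dtype=float)
    Fprime = np.asarray(Fprime, dtype=float)
    if F.shape != Fprime.shape:
        raise ValueError(f"length mismatch: {F.shape} vs {Fprime.shape}")
    mask = F > 0.0
    stat = float(np.sum((Fprime[mask] - F[mask]) ** 2 / F[mask]))
    return stat, int(mask.sum())


def compare(table_a: FrequencyTable, table_b: FrequencyTable) -> ComparisonResult:
    """Align two frequency tables by reaction id and compute both statistics.

    ``table_a`` is the reference side of chi_bar.  The reaction universes
    must coincide; a mismatch error lists the symmetric difference.
    """
    ids_a, ids_b = set(table_a.reaction_ids), set(table_b.reaction_ids)
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"reaction universes differ; unmatched ids: {diff}")
    order = {rid: i for i, rid in enumerate(table_b.reaction_ids)}
    Fa = table_a.F
    Fb = table_b.F[[order[rid] for rid in table_a.reaction_ids]]
    d = Fb - Fa
    chi, pairs_chi = _chi_bar(Fa, Fb)
    return ComparisonResult(
        wilcoxon_p=wilcoxon_signed_rank(Fa, Fb),
        chi_bar=chi,
        pairs_used_wilcoxon=int(np.count_nonzero(d)),
        pairs_used_chibar=pairs_chi,
        N_a=table_a.N,
        N_b=table_b.N,
        p_a=table_a.p,
        p_b=table_b.p,
    )


def write_comparison_tsv(path: str | Path, result: ComparisonResult) -> None:
    """One-row TSV with both statistics and the experiment metadata."""
    header = "wilcoxon_p\tchi_bar\tpairs_used_wilcoxon\tpairs_used_chibar\tN_A\tN_B\tp_A\tp_B"
    row = (
        f"{result.wilcoxon_p:.6g}\t{result.chi_bar:.6g}\t{result.pairs_used_wilcoxon}\t"
        f"{result.pairs_used_chibar}\t{result.N_a}\t{result.N_b}\t"
        f"{result.p_a:.6g}\t{result.p_b:.6g}"
    )
    Path(path).write_text(header + "\n" + row + "\n", encoding="utf-8")
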