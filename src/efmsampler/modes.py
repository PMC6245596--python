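"""Pathway validity, elementarity testing, deduplication and a brute-force oracle.

A pathway of the split network is any nonzero, nonnegative flux vector in the
null space of ``S_split``; it is identified with its support.  An elementary
flux mode (EFM) is a pathway whose support strictly contains no other
pathway's support — equivalently the flux cone restricted to the support is a
single ray, which holds exactly when the support columns of ``S_split`` have
rank ``|support| - 1``.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .network import SplitNetwork
from .extraction import FluxSolution

__all__ = [
    "CanonicalSupport",
    "is_pathway",
    "is_elementary",
    "brute_force_efms",
    "deduplicate",
    "support_exists",
]

CanonicalSupport = tuple[str, ...]
"""A support as a sorted, duplicate-free tuple of split-reaction identifiers."""


def canonical_support(split_net: SplitNetwork, support: Iterable[int]) -> CanonicalSupport:
    """Canonicalize a set of split indices as a sorted id tuple."""
    return tuple(sorted(split_net.split_reaction_ids[i] for i in set(support)))


def is_pathway(split_net: SplitNetwork, v: Sequence[float], tol: float = 1e-9) -> bool:
    """True iff ``v`` is a nonzero, nonnegative steady-state flux vector.

    The residual test is relative: ``||S_split v||_inf <= tol * (1 + ||v||_inf)``.
    The zero vector is rejected — the trivial LP solution carries no
    biological information.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (split_net.n_split,):
        raise ValueError("flux vector length does not match split network")
    vmax = np.abs(v).max()
    if vmax <= tol:
        return False
    if v.min() < -tol:
        return False
    residual = np.abs(split_net.S_split @ v).max()
    return residual <= tol * (1.0 + vmax)


def support_exists(split_net: SplitNetwork, support: Iterable[int]) -> bool:
    """Feasibility check: does a pathway with *exactly* this support exist?

    Solves the LP ``S v = 0, v_j >= 1 on the support, v_j = 0 off it``.
    """
    support = sorted(set(support))
    n = split_net.n_split
    bounds = [(0.0, 0.0)] * n
    for j in support:
        bounds[j] = (1.0, None)
    res = linprog(
        np.zeros(n),
        A_eq=split_net.S_split,
        b_eq=np.zeros(split_net.S_split.shape[0]),
        bounds=bounds,
        method="highs",
    )
    return res.status == 0


def is_elementary(
    split_net: SplitNetwork, support: Iterable[int], check_exists: bool = True
) -> bool:
    """Rank test for support minimality.

    A support ``T`` carried by some pathway is elementary iff
    ``rank(S_split[:, T]) == |T| - 1``: the restricted null space is then
    one-dimensional, so the flux cone on ``T`` is a single ray and no pathway
    can live on a strict subset of ``T``.  Depends on the support only, hence
    invariant to flux rescaling.

    Raises ``ValueError`` when no pathway has exactly this support (the test
    is undefined there); pass ``check_exists=False`` to skip the feasibility
    LP when existence is already known.
    """
    support = sorted(set(support))
    if len(support) == 0:
        raise ValueError("empty support")
    if check_exists and not support_exists(split_net, support):
        raise ValueError("no pathway exists with exactly this support; elementarity undefined")
    sub = split_net.S_split[:, support]
    sv = np.linalg.svd(sub, compute_uv=False)
    rank = int(np.sum(sv > 1e-9 * sv[0])) if sv.size else 0
    return rank == len(support) - 1


def brute_force_efms(split_net: SplitNetwork, max_reactions: int = 15) -> set[CanonicalSupport]:
    """Enumerate all EFM supports of a small split network by exhaustion.

    Subsets of split reactions are tried in increasing size; a subset is an
    EFM support iff a pathway with exactly that support exists (feasibility
    LP) and no previously accepted (hence smaller) support is contained in
    it.  Exponential in the reaction count, so refuses networks above
    ``max_reactions`` split columns.
    """
    n = split_net.n_split
    if n > max_reactions:
        raise ValueError(f"network has {n} split reactions, above the cap of {max_reactions}")
    efms: list[frozenset[int]] = []
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            sset = frozenset(subset)
            if any(e <= sset for e in efms):
                continue
            if support_exists(split_net, sset):
                efms.append(sset)
    return {canonical_support(split_net, e) for e in efms}


def _is_two_cycle(split_net: SplitNetwork, support: frozenset[int]) -> bool:
    """True iff the support is exactly the fwd/bwd split pair of one reaction."""
    if len(support) != 2:
        return False
    origins = {split_net.origin[i][0] for i in support}
    return len(origins) == 1


def deduplicate(
    split_net: SplitNetwork,
    solutions: Sequence[FluxSolution],
    drop_two_cycles: bool = False,
) -> tuple[set[CanonicalSupport], int]:
    """Distinct solution supports and the repetition count.

    With ``drop_two_cycles`` the futile fwd/bwd pairs of single reversible
    reactions — genuine steady-state solutions of the split system but
    biologically vacuous — are removed before counting.
    """
    kept = [
        sol
        for sol in solutions
        if not (drop_two_cycles and _is_two_cycle(split_net, sol.support))
    ]
    distinct = {canonical_support(split_net, sol.support) for sol in kept}
    return distinct, len(kept) - len(distinct)
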