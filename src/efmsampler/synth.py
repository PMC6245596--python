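"""Synthetic fixture networks with known ground truth.

Tiny networks whose complete EFM sets are known by construction (and
checkable with the brute-force oracle) so the extraction machinery can be
exercised end to end without any model download: linear chains, parallel
branch networks (the 2-branch case is the classic "diamond"), and rejection-
sampled random sparse networks guaranteed to admit at least one nontrivial
pathway.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork, split_reversible

__all__ = ["make_chain", "make_parallel", "make_random", "has_nontrivial_pathway"]


def make_chain(L: int, reversible_middle: bool = False) -> MetabolicNetwork:
    """A linear chain: R1 imports M1, Rj converts M(j-1) to Mj, R(L+1) exports ML.

    With all reactions irreversible the unique EFM is the whole chain.  With
    ``reversible_middle`` the middle conversion becomes reversible, adding the
    futile two-cycle of its split pair to the EFM set of the split network.
    """
    if L < 1:
        raise ValueError("chain length L must be >= 1")
    n = L + 1
    S = np.zeros((L, n))
    for j in range(L):
        S[j, j] += 1.0       # reaction j produces metabolite j
        S[j, j + 1] -= 1.0   # reaction j+1 consumes it
    reversible = np.zeros(n, dtype=bool)
    if reversible_middle:
        reversible[n // 2] = True
    return MetabolicNetwork(
        metabolite_ids=tuple(f"M{i + 1}" for i in range(L)),
        reaction_ids=tuple(f"R{j + 1}" for j in range(n)),
        S=S,
        reversible=reversible,
    )


def make_parallel(b: int) -> MetabolicNetwork:
    """Import A, ``b`` parallel conversions A -> B, export B.

    Exactly ``b`` EFMs, each {R_in, branch_i, R_out}; ``b = 2`` is the
    diamond network.  The branch fan-out makes this the canonical testbed
    for solution diversity under penalization.
    """
    if b < 2:
        raise ValueError("branch count b must be >= 2")
    n = b + 2
    S = np.zeros((2, n))
    S[0, 0] = 1.0                    # R_in: -> A
    S[0, 1 : b + 1] = -1.0           # branches consume A
    S[1, 1 : b + 1] = 1.0            # and produce B
    S[1, b + 1] = -1.0               # R_out: B ->
    ids = ["R_in"] + [f"B{i + 1}" for i in range(b)] + ["R_out"]
    return MetabolicNetwork(
        metabolite_ids=("A", "B"),
        reaction_ids=tuple(ids),
        S=S,
        reversible=np.zeros(n, dtype=bool),
    )


def has_nontrivial_pathway(net: MetabolicNetwork) -> bool:
    """Feasibility LP on the split network: S v = 0, v >= 0, sum(v) >= 1."""
    split = split_reversible(net)
    n = split.n_split
    res = linprog(
        np.zeros(n),
        A_eq=split.S_split,
        b_eq=np.zeros(split.S_split.shape[0]),
        A_ub=-np.ones((1, n)),
        b_ub=np.array([-1.0]),
        bounds=[(0.0, None)] * n,
        method="highs",
    )
    return res.status == 0


def make_random(
    m: int,
    n: int,
    density: float = 0.25,
    reversible_fraction: float = 0.0,
    rng_seed: int = 0,
    max_attempts: int = 100,
) -> MetabolicNetwork:
    """Rejection-sample a random sparse integer network with a nontrivial pathway.

    Coefficients are drawn from {-2, -1, 1, 2} with the given placement
    density (integer stoichiometry keeps rank tests exact in the test
    suite).  Random sparse matrices frequently admit only the trivial
    steady-state solution, so candidates are resampled until the feasibility
    LP of :func:`has_nontrivial_pathway` succeeds; after ``max_attempts``
    consecutive rejections the parameters are deemed unworkable.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if n < 2:
        raise ValueError("need at least 2 reactions")
    if not 0 <= reversible_fraction <= 1:
        raise ValueError("reversible_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_attempts):
        mask = rng.random((m, n)) < density
        vals = rng.choice([-2.0, -1.0, 1.0, 2.0], size=(m, n))
        S = np.where(mask, vals, 0.0)
        # a reaction must touch at least one metabolite
        for j in np.flatnonzero(~np.any(S != 0.0, axis=0)):
            i = rng.integers(m)
            S[i, j] = rng.choice([-2.0, -1.0, 1.0, 2.0])
        reversible = rng.random(n) < reversible_fraction
        net = MetabolicNetwork(
            metabolite_ids=tuple(f"M{i + 1}" for i in range(m)),
            reaction_ids=tuple(f"R{j + 1}" for j in range(n)),
            S=S,
            reversible=reversible,
        )
        if has_nontrivial_pathway(net):
            return net
    raise RuntimeError(
        f"no random network with a nontrivial pathway in {max_attempts} attempts; "
        "lower the density or add reactions"
    )
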