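"""Per-iteration linear programs with positive seeds, and the extraction loop.

Each iteration solves

    minimize    sum_i w_i * v_i
    subject to  S_split @ v = 0
                v >= 0
                v_j >= c          for every j in the seed

over the split (all-irreversible) network.  The seed forces a random set of
reactions to carry flux so the solver cannot return the trivial all-zero
solution; the weights ``w_i = 1 + p * F_i`` penalize reactions by how often
they already occurred, steering successive iterations toward less-visited
parts of the network without ever forbidding a reaction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork, SplitNetwork, split_reversible

__all__ = [
    "Seed",
    "LPSettings",
    "FluxSolution",
    "ExtractionState",
    "ExtractionResult",
    "SolverFailure",
    "generate_seed",
    "compute_weights",
    "solve_iteration",
    "update_state",
    "run_extraction",
    "write_solutions_tsv",
    "write_frequency_tsv",
    "read_frequency_tsv",
]

INFEASIBLE = "infeasible"


class SolverFailure(RuntimeError):
    """The LP solver failed for a numerical (retriable) reason, not infeasibility."""


@dataclass(frozen=True)
class Seed:
    """A set of split-reaction indices forced to carry positive flux."""

    reaction_indices: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "reaction_indices", frozenset(self.reaction_indices))
        if len(self.reaction_indices) < 1:
            raise ValueError("a seed needs at least one reaction")
        if any(i < 0 for i in self.reaction_indices):
            raise ValueError("negative split-reaction index in seed")

    @property
    def k(self) -> int:
        return len(self.reaction_indices)


@dataclass(frozen=True)
class LPSettings:
    """Numerical knobs of the per-iteration LP.

    seed_lower_bound
        Flux floor ``c`` imposed on seed reactions.  Any positive value is
        equivalent up to rescaling because the constraint set is a cone.
    support_threshold
        Relative tolerance: a flux counts as nonzero when it exceeds
        ``support_threshold * max(v)``.
    solver_feas_tol
        Primal/dual feasibility tolerance handed to HiGHS.
    """

    seed_lower_bound: float = 1.0
    support_threshold: float = 1e-6
    solver_feas_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.seed_lower_bound <= 0 or self.support_threshold <= 0 or self.solver_feas_tol <= 0:
            raise ValueError("LP settings must be strictly positive")
        if self.support_threshold >= 1:
            raise ValueError("support_threshold must be < 1")


@dataclass
class FluxSolution:
    """One feasible LP outcome: flux vector, its support and provenance."""

    v: np.ndarray
    support: frozenset[int]
    seed: Seed
    objective: float
    elementary: bool | None = None


@dataclass
class ExtractionState:
    """Running occurrence counts, frequencies and penalized weights.

    Invariants maintained by :func:`update_state`: ``F = O / N`` whenever
    ``N > 0``, ``O_i <= N`` and ``1 <= w_i <= 1 + p``.
    """

    n_split: int
    p: float
    N: int = 0
    O: np.ndarray = None  # type: ignore[assignment]
    F: np.ndarray = None  # type: ignore[assignment]
    w: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("penalization p must be >= 0")
        if self.O is None:
            self.O = np.zeros(self.n_split, dtype=np.int64)
        if self.F is None:
            self.F = np.zeros(self.n_split)
        if self.w is None:
            self.w = np.ones(self.n_split)


@dataclass
class ExtractionResult:
    """Outcome of a full extraction experiment."""

    solutions: list[FluxSolution]
    state: ExtractionState
    infeasible_count: int
    status: Literal["completed", "drought"]


def generate_seed(rng: np.random.Generator, n_split: int, k: int) -> Seed:
    """Draw ``k`` distinct split-reaction indices uniformly without replacement."""
    if not 1 <= k <= n_split:
        raise ValueError(f"seed size k={k} must be in 1..{n_split}")
    idx = rng.choice(n_split, size=k, replace=False)
    return Seed(frozenset(int(i) for i in idx))


def compute_weights(F: Sequence[float], p: float) -> np.ndarray:
    """Penalized objective weights ``w_i = 1 + p * F_i``."""
    F = np.asarray(F, dtype=float)
    if p < 0:
        raise ValueError("penalization p must be >= 0")
    if np.any(F < 0) or np.any(F > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    return 1.0 + p * F


def solve_iteration(
    split_net: SplitNetwork,
    seed: Seed,
    w: Sequence[float],
    settings: LPSettings = LPSettings(),
) -> FluxSolution | str:
    """Solve one penalized LP; return a :class:`FluxSolution` or ``"infeasible"``.

    The program is always bounded below (nonnegative costs over the
    nonnegative orthant), so the only solver outcomes are optimality and
    infeasibility; anything else is raised as :class:`SolverFailure`.
    """
    n = split_net.n_split
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError("weight vector length does not match split network")
    if np.any(w < 1.0 - 1e-12):
        raise ValueError("weights must be >= 1 elementwise")
    if any(i >= n for i in seed.reaction_indices):
        raise ValueError("seed index out of range for this split network")
    c = settings.seed_lower_bound
    bounds = [(0.0, None)] * n
    for j in seed.reaction_indices:
        bounds[j] = (c, None)
    res = linprog(
        w,
        A_eq=split_net.S_split,
        b_eq=np.zeros(split_net.S_split.shape[0]),
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": settings.solver_feas_tol,
            "dual_feasibility_tolerance": settings.solver_feas_tol,
        },
    )
    if res.status == 2:
        return INFEASIBLE
    if res.status != 0:
        raise SolverFailure(f"HiGHS status {res.status}: {res.message}")
    v = np.maximum(res.x, 0.0)
    support = frozenset(np.flatnonzero(v > settings.support_threshold * v.max()).tolist())
    return FluxSolution(v=v, support=support, seed=seed, objective=float(res.fun))


def update_state(state: ExtractionState, sol: FluxSolution) -> ExtractionState:
    """Fold one feasible solution into the running counts (in place; returned).

    Repeated identical solutions still increment the occurrences: the
    frequency is defined per iteration, ``F_i = O_i / N``, so it stays in
    [0, 1] only if every counted iteration contributes.
    """
    state.N += 1
    idx = np.fromiter(sol.support, dtype=np.int64)
    state.O[idx] += 1
    state.F = state.O / state.N
    state.w = compute_weights(state.F, state.p)
    return state


def _seed_is_two_cycle(split_net: SplitNetwork, seed: Seed) -> bool:
    """True if the seed contains both split directions of one reversible reaction."""
    origins = [split_net.origin[i][0] for i in seed.reaction_indices]
    return len(set(origins)) < len(origins)


def run_extraction(
    net: MetabolicNetwork | SplitNetwork,
    N_target: int,
    p: float = 0.0,
    k: int = 4,
    rng_seed: int | np.random.Generator = 0,
    settings: LPSettings = LPSettings(),
    weight_mode: Literal["dynamic", "static", "off"] = "dynamic",
    F0: Sequence[float] | None = None,
    drought_cap: int = 1000,
    allow_two_cycle_seeds: bool = True,
) -> ExtractionResult:
    """Collect ``N_target`` feasible LP solutions with random positive seeds.

    Per iteration a fresh seed of ``k`` uniformly drawn split reactions is
    imposed; infeasible seeds are discarded without advancing the iteration
    counter (frequencies are defined over solutions, not attempts).  Weight
    handling per ``weight_mode``:

    - ``"dynamic"``: recomputed from the running frequencies before each
      iteration (the default protocol),
    - ``"static"``: fixed at ``1 + p * F0`` from a supplied frequency vector,
      e.g. the outcome of a previous unpenalized run,
    - ``"off"``: identically 1, the unpenalized base program.

    A run aborts with ``status="drought"`` after ``drought_cap`` consecutive
    infeasible seeds, returning the solutions gathered so far.
    """
    if N_target < 1:
        raise ValueError("N_target must be >= 1")
    split_net = net if isinstance(net, SplitNetwork) else split_reversible(net)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    state = ExtractionState(n_split=split_net.n_split, p=p)
    if weight_mode == "static":
        if F0 is None:
            raise ValueError("weight_mode='static' requires F0")
        static_w = compute_weights(F0, p)
    solutions: list[FluxSolution] = []
    infeasible = 0
    consecutive_infeasible = 0
    status: Literal["completed", "drought"] = "completed"
    while state.N < N_target:
        seed = generate_seed(rng, split_net.n_split, k)
        if not allow_two_cycle_seeds and _seed_is_two_cycle(split_net, seed):
            continue
        if weight_mode == "dynamic":
            w = state.w
        elif weight_mode == "static":
            w = static_w
        else:
            w = np.ones(split_net.n_split)
        out = solve_iteration(split_net, seed, w, settings)
        if out == INFEASIBLE:
            infeasible += 1
            consecutive_infeasible += 1
            if consecutive_infeasible >= drought_cap:
                status = "drought"
                break
            continue
        consecutive_infeasible = 0
        solutions.append(out)
        update_state(state, out)
    return ExtractionResult(
        solutions=solutions, state=state, infeasible_count=infeasible, status=status
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_solutions_tsv(
    path: str | Path,
    split_net: SplitNetwork,
    solutions: Iterable[FluxSolution],
    header_lines: Sequence[str] = (),
) -> None:
    """One row per solution: iteration, seed ids, support ids, objective, fluxes."""
    ids = split_net.split_reaction_ids
    lines = [f"# {h}" for h in header_lines]
    lines.append("iteration\tseed\tsupport\tobjective\telementary\tfluxes")
    for it, sol in enumerate(solutions, start=1):
        seed_ids = ",".join(ids[i] for i in sorted(sol.seed.reaction_indices))
        supp = sorted(sol.support)
        supp_ids = ",".join(ids[i] for i in supp)
        fluxes = ",".join(f"{ids[i]}={sol.v[i]:.10g}" for i in supp)
        elem = "" if sol.elementary is None else str(int(sol.elementary))
        lines.append(f"{it}\t{seed_ids}\t{supp_ids}\t{sol.objective:.10g}\t{elem}\t{fluxes}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_frequency_tsv(
    path: str | Path,
    split_net: SplitNetwork,
    state: ExtractionState,
    header_lines: Sequence[str] = (),
) -> None:
    """Reaction occurrence/frequency table with N and p recorded as comments."""
    lines = [f"# {h}" for h in header_lines]
    lines.append(f"# N={state.N}")
    lines.append(f"# p={state.p:.10g}")
    lines.append("reaction_id\toccurrences\tfrequency\tfinal_weight")
    for i, rid in enumerate(split_net.split_reaction_ids):
        lines.append(f"{rid}\t{state.O[i]}\t{state.F[i]:.10g}\t{state.w[i]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_frequency_tsv(path: str | Path):
    """Read a frequency table written by :func:`write_frequency_tsv`.

    Returns a :class:`efmsampler.stats.FrequencyTable`.
    """
    from .stats import FrequencyTable

    meta: dict[str, str] = {}
    ids: list[str] = []
    occ: list[int] = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln:
            continue
        if ln.startswith("#"):
            body = ln[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        cells = ln.split("\t")
        if cells[0] == "reaction_id":
            continue
        ids.append(cells[0])
        occ.append(int(cells[1]))
    if "N" not in meta:
        raise ValueError(f"{path}: missing '# N=' metadata line")
    return FrequencyTable(
        reaction_ids=tuple(ids),
        O=np.array(occ, dtype=np.int64),
        N=int(meta["N"]),
        p=float(meta.get("p", "nan")),
    )
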