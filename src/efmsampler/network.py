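"""Stoichiometric network containers, model readers and reversible-reaction splitting.

A metabolic network is held as a dense stoichiometric matrix ``S`` (rows =
metabolites, columns = reactions) together with reaction/metabolite
identifiers and per-reaction reversibility flags.  Because the downstream
linear programs require all fluxes to be nonnegative, every reversible
reaction is "de-doubled" into a forward and a backward irreversible column
before any LP is built; :class:`SplitNetwork` keeps the back-mapping so that
split-level supports can be reported in terms of the original reactions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Direction",
    "MetabolicNetwork",
    "SplitNetwork",
    "ValidationError",
    "FormatError",
    "read_model",
    "read_tsv",
    "write_tsv",
    "split_reversible",
    "project_support",
]


class ValidationError(ValueError):
    """A model violates a structural invariant (duplicate ids, empty, zero column)."""


class FormatError(ValueError):
    """A model file could not be parsed in the declared format."""


class Direction(str, enum.Enum):
    """Direction of a split column relative to its source reaction."""

    forward = "forward"
    backward = "backward"


@dataclass(frozen=True)
class MetabolicNetwork:
    """A stoichiometric model: matrix, identifiers and reversibility flags.

    Parameters
    ----------
    metabolite_ids
        Unique metabolite identifiers; one per row of ``S``.
    reaction_ids
        Unique reaction identifiers; one per column of ``S``.
    S
        Stoichiometric coefficients, shape ``(n_metabolites, n_reactions)``.
        Positive entries produce the row metabolite, negative consume it.
    reversible
        Boolean flag per reaction; reversible reactions are split before LP use.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: np.ndarray
    reversible: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        rev = np.asarray(self.reversible, dtype=bool)
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "reversible", rev)
        if len(self.metabolite_ids) == 0 or len(self.reaction_ids) == 0:
            raise ValidationError("empty model: needs at least one metabolite and one reaction")
        if S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise ValidationError(
                f"S has shape {S.shape}, expected "
                f"({len(self.metabolite_ids)}, {len(self.reaction_ids)})"
            )
        if rev.shape != (len(self.reaction_ids),):
            raise ValidationError("reversible flags must align with reaction_ids")
        for kind, ids in (("metabolite", self.metabolite_ids), ("reaction", self.reaction_ids)):
            if len(set(ids)) != len(ids):
                dups = sorted({i for i in ids if list(ids).count(i) > 1})
                raise ValidationError(f"duplicate {kind} identifiers: {dups}")
        zero_cols = np.flatnonzero(~np.any(S != 0.0, axis=0))
        if zero_cols.size:
            bad = [self.reaction_ids[j] for j in zero_cols]
            raise ValidationError(f"all-zero stoichiometry column(s): {bad}")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_reversible(self) -> int:
        return int(self.reversible.sum())


@dataclass(frozen=True)
class SplitNetwork:
    """An all-irreversible ("de-doubled") view of a :class:`MetabolicNetwork`.

    Every reversible source reaction contributes a forward column (unchanged)
    and a backward column (negated); irreversible reactions contribute their
    single column verbatim.  ``origin[j]`` records, for split column ``j``,
    the index of the source reaction and the direction.
    """

    source: MetabolicNetwork
    split_reaction_ids: tuple[str, ...]
    S_split: np.ndarray
    origin: tuple[tuple[int, Direction], ...]

    @property
    def n_split(self) -> int:
        return len(self.split_reaction_ids)

    def index_of(self, split_id: str) -> int:
        return self.split_reaction_ids.index(split_id)


def split_reversible(net: MetabolicNetwork) -> SplitNetwork:
    """De-double reversible reactions into forward/backward irreversible pairs.

    Split identifiers are the original id suffixed ``_fwd``/``_bwd`` for
    reversible reactions; irreversible reactions keep their id verbatim.
    Column count of the result is ``n + n_reversible``.
    """
    cols: list[np.ndarray] = []
    ids: list[str] = []
    origin: list[tuple[int, Direction]] = []
    for j, rid in enumerate(net.reaction_ids):
        col = net.S[:, j]
        if net.reversible[j]:
            ids.append(f"{rid}_fwd")
            cols.append(col)
            origin.append((j, Direction.forward))
            ids.append(f"{rid}_bwd")
            cols.append(-col)
            origin.append((j, Direction.backward))
        else:
            ids.append(rid)
            cols.append(col)
            origin.append((j, Direction.forward))
    return SplitNetwork(
        source=net,
        split_reaction_ids=tuple(ids),
        S_split=np.column_stack(cols),
        origin=tuple(origin),
    )


def project_support(
    split_net: SplitNetwork, support: Iterable[int]
) -> set[tuple[str, Direction]]:
    """Map split-column indices back to ``(original reaction id, direction)`` pairs.

    Both directions of a reversible reaction remain distinct in the output,
    so a two-cycle stays visible after projection.
    """
    out: set[tuple[str, Direction]] = set()
    for idx in support:
        if not 0 <= idx < split_net.n_split:
            raise IndexError(f"split index {idx} out of range 0..{split_net.n_split - 1}")
        j, direction = split_net.origin[idx]
        out.add((split_net.source.reaction_ids[j], direction))
    return out


# ---------------------------------------------------------------------------
# TSV dialect
#
# row 1: "metabolite" <tab> reaction ids...
# row 2: "reversible" <tab> 0/1 flags...
# rows 3+: metabolite id <tab> coefficients...  ("." decimal, UTF-8)
# Lines starting with "#" are comments and ignored on read.
# ---------------------------------------------------------------------------


def write_tsv(net: MetabolicNetwork, path: str | Path) -> None:
    """Write a network in the package TSV dialect (bit-exact round trip)."""
    lines = ["metabolite\t" + "\t".join(net.reaction_ids)]
    lines.append("reversible\t" + "\t".join("1" if r else "0" for r in net.reversible))
    for i, mid in enumerate(net.metabolite_ids):
        lines.append(mid + "\t" + "\t".join(repr(float(x)) for x in net.S[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tsv(path: str | Path) -> MetabolicNetwork:
    """Read a network from the package TSV dialect."""
    raw = Path(path).read_text(encoding="utf-8")
    rows = [ln.split("\t") for ln in raw.splitlines() if ln and not ln.startswith("#")]
    if len(rows) < 3:
        raise FormatError(f"{path}: need a header, a reversible row and >=1 metabolite row")
    header, rev_row = rows[0], rows[1]
    if header[0] != "metabolite" or rev_row[0] != "reversible":
        raise FormatError(f"{path}: expected 'metabolite' and 'reversible' leader cells")
    reaction_ids = header[1:]
    if len(rev_row) != len(header):
        raise FormatError(f"{path}: reversible row length mismatch")
    try:
        reversible = np.array([bool(int(x)) for x in rev_row[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: reversible flags must be 0/1 ({exc})") from None
    metabolite_ids: list[str] = []
    coeffs: list[list[float]] = []
    for row in rows[2:]:
        if len(row) != len(header):
            raise FormatError(f"{path}: row for '{row[0]}' has {len(row) - 1} coefficients, "
                              f"expected {len(reaction_ids)}")
        metabolite_ids.append(row[0])
        try:
            coeffs.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: bad coefficient in row '{row[0]}': {exc}") from None
    return MetabolicNetwork(
        metabolite_ids=tuple(metabolite_ids),
        reaction_ids=tuple(reaction_ids),
        S=np.array(coeffs, dtype=float),
        reversible=reversible,
    )


def from_cobra(model, open_exchanges: bool = False) -> MetabolicNetwork:
    """Convert a cobrapy model.

    Reversibility is taken from the flux bounds: lower bound < 0 means
    reversible; bound magnitudes are otherwise discarded (the steady-state
    cone has no finite bounds).  With ``open_exchanges=True`` every boundary
    pseudo-reaction (exchange/demand/sink) is treated as reversible regardless
    of the bounds stored in the file: medium-specific uptake limits are an
    environmental context, not part of the network structure.
    """
    from cobra.util.array import create_stoichiometric_matrix

    if len(model.reactions) == 0 or len(model.metabolites) == 0:
        raise ValidationError(f"model '{model.id}' is empty")
    S = create_stoichiometric_matrix(model, array_type="dense")
    rev = np.array(
        [r.lower_bound < 0 or (open_exchanges and r.boundary) for r in model.reactions]
    )
    return MetabolicNetwork(
        metabolite_ids=tuple(m.id for m in model.metabolites),
        reaction_ids=tuple(r.id for r in model.reactions),
        S=S,
        reversible=rev,
    )


def read_model(
    path: str | Path, format: str | None = None, open_exchanges: bool = False
) -> MetabolicNetwork:
    """Read a metabolic model from SBML, COBRA-JSON or the package TSV dialect.

    ``format`` is one of ``{"sbml", "cobra-json", "tsv"}``; when omitted it is
    auto-detected from the extension (``.xml``/``.sbml`` -> sbml, ``.json`` ->
    cobra-json, ``.tsv`` -> tsv).  ``open_exchanges`` only affects SBML/JSON
    input (see :func:`from_cobra`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".xml", ".sbml"} or path.name.endswith(".xml.gz"):
            format = "sbml"
        elif suffix == ".json":
            format = "cobra-json"
        elif suffix == ".tsv":
            format = "tsv"
        else:
            raise FormatError(f"cannot auto-detect model format from '{path.name}'")
    if format == "tsv":
        return read_tsv(path)
    import cobra.io

    try:
        if format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        elif format == "cobra-json":
            model = cobra.io.load_json_model(str(path))
        else:
            raise FormatError(f"unknown format '{format}'")
    except FormatError:
        raise
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise FormatError(f"could not parse '{path}' as {format}: {exc}") from exc
    return from_cobra(model, open_exchanges=open_exchanges)


def net_flux(split_net: SplitNetwork, v_split: Sequence[float]) -> np.ndarray:
    """Project a split-level flux vector to net flux per source reaction.

    Net flux of a reversible reaction is forward minus backward flux; the
    projection preserves the steady state: ``S @ net_flux == S_split @ v``.
    """
    v_split = np.asarray(v_split, dtype=float)
    if v_split.shape != (split_net.n_split,):
        raise ValueError("flux vector length does not match split network")
    out = np.zeros(split_net.source.n_reactions)
    for j, (orig, direction) in enumerate(split_net.origin):
        out[orig] += v_split[j] if direction is Direction.forward else -v_split[j]
    return out
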