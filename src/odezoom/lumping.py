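"""Proper lumping schemes for the modified lumped state variables.

A proper scheme is a binary matrix ``M_m`` with unit column sums over the
fast species: every fast species contributes to exactly one lump.  Each
lump must take its members from the support of one (apparent or exact)
conservation relation; lumps that coincide with an exact conservation are
replaced by constants in the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp
from scipy.optimize import linprog

from .conservation import ConservationBasis
from .network import NetworkError

__all__ = [
    "Lump",
    "LumpingScheme",
    "ValidationReport",
    "validate_proper",
    "build_scheme",
    "reduction_summary",
    "ImproperSchemeError",
]


class ImproperSchemeError(NetworkError):
    """A requested lumping scheme violates properness."""


@dataclass(frozen=True)
class Lump:
    """One modified lumped state variable."""

    name: str
    members: tuple[str, ...]  # ordered by species order
    parent: tuple[int, ...]  # conservation row over the fast species it sub-lumps
    parent_name: str
    constant: bool = False  # retained exact conservation -> constant

    @property
    def width(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LumpingScheme:
    lumps: tuple[Lump, ...]
    fast_species: tuple[str, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(lp.name for lp in self.lumps)

    @property
    def matrix(self) -> sp.ImmutableMatrix:
        """M_m: binary, rows = lumps, columns = fast species."""
        return sp.ImmutableMatrix(
            [
                [1 if s in lp.members else 0 for s in self.fast_species]
                for lp in self.lumps
            ]
        )

    @property
    def parent_matrix(self) -> sp.ImmutableMatrix:
        return sp.ImmutableMatrix([list(lp.parent) for lp in self.lumps])

    def lump_of(self, species: str) -> Lump:
        for lp in self.lumps:
            if species in lp.members:
                return lp
        raise KeyError(species)

    def by_name(self, name: str) -> Lump:
        for lp in self.lumps:
            if lp.name == name:
                return lp
        raise KeyError(name)

    def constants(self) -> tuple[Lump, ...]:
        return tuple(lp for lp in self.lumps if lp.constant)

    def dynamic(self) -> tuple[Lump, ...]:
        return tuple(lp for lp in self.lumps if not lp.constant)

    def apply(self, state: dict[str, float]) -> dict[str, float]:
        """lm = M_m x at a numeric state."""
        return {
            lp.name: float(sum(state[s] for s in lp.members)) for lp in self.lumps
        }


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...]


def _support_in_cone(indicator: np.ndarray, basis_rows: np.ndarray) -> bool:
    """Is there a vector in the row span of ``basis_rows`` that is >= 0
    everywhere and >= 1 on the indicator's support?  (LP feasibility.)"""
    if basis_rows.size == 0:
        return False
    lower = np.where(indicator > 0, 1.0, 0.0)
    # find c with basis^T c >= lower
    res = linprog(
        c=np.zeros(basis_rows.shape[0]),
        A_ub=-basis_rows.T,
        b_ub=-lower,
        bounds=[(None, None)] * basis_rows.shape[0],
        method="highs",
    )
    return bool(res.success)


def validate_proper(
    Mm: sp.Matrix | LumpingScheme,
    apparent: ConservationBasis,
    names: tuple[str, ...] | None = None,
) -> ValidationReport:
    """Check the three properness conditions against an apparent basis.

    A lump whose members are not covered by the support of any single basis
    row is still admitted if some nonnegative combination of basis rows
    (i.e. some other apparent conservation relation) covers it.
    """
    if isinstance(Mm, LumpingScheme):
        names = Mm.names
        Mm = Mm.matrix
    M = sp.Matrix(Mm)
    b, nf = M.shape
    if names is None:
        names = tuple(f"lm{i + 1}" for i in range(b))
    violations: list[str] = []
    for i in range(b):
        for j in range(nf):
            if M[i, j] not in (0, 1):
                violations.append(f"row {names[i]}, column {apparent.species[j]}: entry {M[i, j]} not in {{0,1}}")
    for j in range(nf):
        csum = sum(M[i, j] for i in range(b))
        if csum != 1:
            violations.append(
                f"column sum != 1 for species {apparent.species[j]} (got {csum})"
            )
    basis_np = np.array(apparent.rows.tolist(), dtype=float) if apparent.n_rows else np.zeros((0, nf))
    supports = [frozenset(k for k, v in enumerate(row) if v) for row in apparent.rows.tolist()]
    for i in range(b):
        member_idx = frozenset(j for j in range(nf) if M[i, j] == 1)
        if not member_idx:
            violations.append(f"row {names[i]} is empty")
            continue
        if len(member_idx) == 1:
            continue  # singleton lumps are trivially admissible
        if any(member_idx <= s for s in supports):
            continue
        ind = np.array([1.0 if j in member_idx else 0.0 for j in range(nf)])
        if not _support_in_cone(ind, basis_np):
            members = [apparent.species[j] for j in sorted(member_idx)]
            violations.append(
                f"row {names[i]}: members {members} not covered by any apparent "
                "conservation relation"
            )
    return ValidationReport(ok=not violations, violations=tuple(violations))


def _restrict_exact_row(
    row: tuple[int, ...],
    exact: ConservationBasis,
    fast_species: tuple[str, ...],
) -> tuple[int, ...] | None:
    """Restrict an exact conservation row to the fast species; None if it
    has support outside them (then it is not usable as a lump/parent)."""
    vals = dict(zip(exact.species, row))
    if any(v for s, v in vals.items() if s not in fast_species):
        return None
    return tuple(vals.get(s, 0) for s in fast_species)


def build_scheme(
    apparent: ConservationBasis,
    exact: ConservationBasis | None,
    keep: list[str],
    assignment: dict[str, list[str]] | None = None,
) -> LumpingScheme:
    """Deterministically assemble a proper scheme.

    ``keep`` names conservation rows (apparent first, then exact) retained
    with their full member sets.  Leftover fast species are grouped per
    ``assignment`` and otherwise become singleton lumps, in species order.
    Kept lumps equal to an exact conservation row are marked constant.
    """
    fast_species = apparent.species
    nf = len(fast_species)
    assignment = dict(assignment or {})

    exact_rows: dict[str, tuple[int, ...]] = {}
    if exact is not None:
        for i, nm in enumerate(exact.names):
            r = _restrict_exact_row(exact.row(i), exact, fast_species)
            if r is not None:
                exact_rows[nm] = r

    def find_row(name: str) -> tuple[int, ...]:
        if name in apparent.names:
            return apparent.row_by_name(name)
        if name in exact_rows:
            return exact_rows[name]
        raise ImproperSchemeError(f"kept lump {name!r} matches no conservation row")

    exact_span = (
        sp.Matrix([list(r) for r in exact_rows.values()])
        if exact_rows
        else sp.zeros(0, nf)
    )

    def is_exact(vec: tuple[int, ...]) -> bool:
        if exact_span.shape[0] == 0:
            return False
        stacked = exact_span.col_join(sp.Matrix([list(vec)]))
        return stacked.rank() == exact_span.rank()

    lumps: list[Lump] = []
    taken: dict[str, str] = {}
    used_parents: set[str] = set()
    for name in keep:
        if name in assignment:
            continue  # an explicitly assigned sub-lump, handled below
        row = find_row(name)
        if any(v not in (0, 1) for v in row):
            raise ImproperSchemeError(
                f"kept lump {name!r} has non-binary coefficients {row}"
            )
        members = tuple(s for s, v in zip(fast_species, row) if v)
        overlap = [s for s in members if s in taken]
        if overlap:
            raise ImproperSchemeError(
                f"improper scheme: kept lumps {taken[overlap[0]]!r} and {name!r} "
                f"share species {overlap}"
            )
        for s in members:
            taken[s] = name
        lumps.append(Lump(name, members, row, name, constant=is_exact(row)))
        used_parents.add(name)

    def parent_for(members: tuple[str, ...]) -> tuple[str, tuple[int, ...]]:
        member_set = set(members)
        candidates = [
            (nm, apparent.row_by_name(nm)) for nm in apparent.names
        ] + list(exact_rows.items())
        for prefer_unused in (True, False):
            for nm, row in candidates:
                if prefer_unused and nm in used_parents:
                    continue
                support = {s for s, v in zip(fast_species, row) if v}
                if member_set <= support:
                    used_parents.add(nm)
                    return nm, row
        raise ImproperSchemeError(
            f"no conservation relation covers members {sorted(member_set)}"
        )

    for lump_name, members in assignment.items():
        members = tuple(s for s in fast_species if s in set(members))
        overlap = [s for s in members if s in taken]
        if overlap:
            raise ImproperSchemeError(
                f"assignment lump {lump_name!r} overlaps {taken[overlap[0]]!r} "
                f"on {overlap}"
            )
        for s in members:
            taken[s] = lump_name
        pname, prow = parent_for(members)
        indicator = tuple(1 if s in members else 0 for s in fast_species)
        lumps.append(Lump(lump_name, members, prow, pname, constant=is_exact(indicator)))

    for s in fast_species:
        if s in taken:
            continue
        taken[s] = s
        pname, prow = parent_for((s,))
        indicator = tuple(1 if sp_ == s else 0 for sp_ in fast_species)
        lumps.append(Lump(s, (s,), prow, pname, constant=is_exact(indicator)))

    scheme = LumpingScheme(tuple(lumps), fast_species)
    report = validate_proper(scheme, apparent)
    if not report.ok:
        raise ImproperSchemeError("; ".join(report.violations))
    return scheme


def reduction_summary(scheme: LumpingScheme, reduced=None) -> dict:
    """State/constant/parameter counts for a reduced model.

    The parameter count requires the symbolically derived reduced model and
    counts rate constants appearing only as ratios (e.g. k1/k-1) once.
    """
    out = {
        "lumps": len(scheme.lumps),
        "constants": len(scheme.constants()),
        "dynamic_states": len(scheme.dynamic()),
    }
    if reduced is not None:
        from .reduction import count_parameters

        out["dynamic_states"] = len(reduced.states)
        out["parameters"] = count_parameters(reduced)
    return out
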