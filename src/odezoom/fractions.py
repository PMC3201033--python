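"""Fraction parameters: the state-dependent back-translation map.

For a lump ``l`` with members ``x_1..x_w`` the fraction parameters are
``eta_i = x_i / l``, obtained by solving a set of relations that are
jointly linear in the members: quasi-steady-state balances of the fast
reactions, exact conservation relations, the lump's own definition, and
optional extra constraints.  Symbols belonging to other lumps are frozen
as coefficients, which is what makes nonlinear mass-action balances
usable as linear relations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import sympy as sp

from .conservation import (
    ConservationBasis,
    FastSlowPartition,
    exact_conservations,
)
from .lumping import Lump, LumpingScheme
from .network import NetworkError, ReactionNetwork, stoichiometric_matrix

__all__ = [
    "Relation",
    "LinearRelationSet",
    "LumpFractions",
    "FractionParameterSet",
    "NonBackTranslatableError",
    "collect_relations",
    "solve_fractions",
    "solve_all",
    "fractions_with_constraint",
]

_PROVENANCE_ORDER = {"lump": 0, "qss": 1, "conservation": 2, "extra": 3}


class NonBackTranslatableError(NetworkError):
    """No nonsingular linear system exists for a lump's members."""


@dataclass(frozen=True)
class Relation:
    """A relation written in residual form ``expr == 0``."""

    expr: sp.Expr
    provenance: str  # lump | qss | conservation | extra
    label: str = ""


@dataclass(frozen=True)
class LinearRelationSet:
    lump: Lump
    relations: tuple[Relation, ...]

    @property
    def n_m(self) -> int:
        return self.lump.width


@dataclass(frozen=True)
class LumpFractions:
    lump: Lump
    eta: dict[str, sp.Expr]  # member -> fraction (may reference foreign species)
    relations_used: tuple[Relation, ...]

    def g_raw(self) -> dict[str, sp.Expr]:
        """member -> eta * lump, cancelled so zero lumps give zero members."""
        L = sp.Symbol(self.lump.name)
        return {m: _tidy(e * L) for m, e in self.eta.items()}


@dataclass
class FractionParameterSet:
    scheme: LumpingScheme
    solved: dict[str, LumpFractions] = field(default_factory=dict)
    unsolved: dict[str, str] = field(default_factory=dict)  # lump name -> reason

    def g_raw(self) -> dict[str, sp.Expr]:
        out: dict[str, sp.Expr] = {}
        for lf in self.solved.values():
            out.update(lf.g_raw())
        return out

    def g(self) -> dict[str, sp.Expr]:
        """Composed back-translation: each fast species as a function of the
        lumped states and parameters only (foreign species substituted out)."""
        raw = self.g_raw()
        state_syms = {sp.Symbol(lp.name) for lp in self.scheme.lumps}
        species_syms = {sp.Symbol(s) for s in self.scheme.fast_species}
        # symbols that must disappear: fast species that are not themselves states
        to_resolve = {
            s for s in species_syms if s not in state_syms
        }
        subs = {sp.Symbol(m): e for m, e in raw.items()}
        out = dict(raw)
        for _ in range(len(self.scheme.lumps) + 1):
            dirty = False
            for m, e in out.items():
                if e.free_symbols & to_resolve:
                    out[m] = _tidy(e.subs(subs))
                    dirty = True
            if not dirty:
                return out
        bad = sorted(
            str(s)
            for e in out.values()
            for s in (e.free_symbols & to_resolve)
        )
        raise NonBackTranslatableError(
            f"cyclic fraction-parameter dependency through {bad}"
        )

    def eta_of(self, species: str) -> sp.Expr:
        for lf in self.solved.values():
            if species in lf.eta:
                return lf.eta[species]
        raise KeyError(species)

    def missing_species(self) -> tuple[str, ...]:
        covered = {m for lf in self.solved.values() for m in lf.eta}
        return tuple(
            s for s in self.scheme.fast_species if s not in covered
        )


def _is_linear_in(expr: sp.Expr, members: tuple[sp.Symbol, ...]) -> bool:
    """Joint total degree <= 1 in the member symbols (others frozen)."""
    try:
        poly = sp.Poly(sp.expand(expr), *members)
    except sp.PolynomialError:
        return False
    return poly.total_degree() <= 1


def collect_relations(
    network: ReactionNetwork,
    part: FastSlowPartition,
    scheme: LumpingScheme,
    lump: str | Lump,
    extra: list[sp.Expr] | None = None,
    sources: tuple[str, ...] = ("lump", "qss", "conservation", "extra"),
    exact: ConservationBasis | None = None,
) -> LinearRelationSet:
    """All relations involving the lump's members that pass the per-lump
    joint-linearity check, tagged with provenance."""
    lp = scheme.by_name(lump) if isinstance(lump, str) else lump
    member_syms = tuple(sp.Symbol(m) for m in lp.members)
    candidates: list[Relation] = []

    if "lump" in sources:
        candidates.append(
            Relation(
                sp.Add(*member_syms) - sp.Symbol(lp.name), "lump", f"def {lp.name}"
            )
        )
    if "qss" in sources:
        for i, eq in enumerate(part.balance_equations()):
            candidates.append(Relation(eq, "qss", f"balance {i + 1}"))
    if "conservation" in sources:
        if exact is None:
            exact = exact_conservations(stoichiometric_matrix(network))
        for nm, e in exact.expressions().items():
            candidates.append(Relation(e - sp.Symbol(nm), "conservation", nm))
    if "extra" in sources:
        for i, e in enumerate(extra or []):
            if isinstance(e, sp.Equality):
                e = e.lhs - e.rhs
            candidates.append(Relation(sp.sympify(e), "extra", f"extra {i + 1}"))

    kept = []
    for rel in candidates:
        if not (rel.expr.free_symbols & set(member_syms)):
            continue
        if not _is_linear_in(rel.expr, member_syms):
            continue
        kept.append(rel)
    kept.sort(key=lambda r: _PROVENANCE_ORDER[r.provenance])
    return LinearRelationSet(lp, tuple(kept))


_TIDY_OPS = 600


def _tidy(expr: sp.Expr) -> sp.Expr:
    """Cancel small expressions to their canonical rational form; leave
    large ones untouched (GCD on big multivariate polys is prohibitive)."""
    if sp.count_ops(expr) < _TIDY_OPS:
        return sp.cancel(expr)
    return expr


def solve_fractions(relset: LinearRelationSet) -> LumpFractions:
    """Pick the first symbolically nonsingular n_m-subset of relations (in
    provenance order: lump definition, QSS, conservation, extra), solve for
    the members by Cramer's rule on the denominator-cleared system, and
    normalise to fractions with sum(eta) == 1 (verified by polynomial
    expansion of the cross-multiplied difference)."""
    lp = relset.lump
    n_m = relset.n_m
    member_syms = [sp.Symbol(m) for m in lp.members]
    L = sp.Symbol(lp.name)
    if len(relset.relations) < n_m:
        raise NonBackTranslatableError(
            f"lump {lp.name!r}: {len(relset.relations)} usable relations < "
            f"{n_m} members"
        )
    for subset in itertools.combinations(relset.relations, n_m):
        A, b = sp.linear_eq_to_matrix([r.expr for r in subset], member_syms)
        # clear row denominators so all determinant work is polynomial
        for i in range(n_m):
            entries = [sp.cancel(A[i, j]) for j in range(n_m)] + [sp.cancel(b[i])]
            lc = sp.lcm([sp.fraction(e)[1] for e in entries])
            for j in range(n_m):
                A[i, j] = sp.expand(sp.cancel(entries[j] * lc))
            b[i] = sp.expand(sp.cancel(entries[n_m] * lc))
        det = sp.expand(A.det(method="berkowitz"))
        if det == 0:
            continue
        nums = []
        for i in range(n_m):
            Ai = A.copy()
            Ai[:, i] = b
            nums.append(sp.expand(Ai.det(method="berkowitz")))
        # normalisation requires sum(members) == L identically
        if sp.expand(sp.Add(*nums) - L * det) != 0:
            continue
        eta = {m: _tidy(x / (L * det)) for m, x in zip(lp.members, nums)}
        # residual check: the solution satisfies every chosen relation,
        # verified on the cleared (polynomial) system
        for i in range(n_m):
            res = sp.expand(
                sp.Add(*(A[i, j] * nums[j] for j in range(n_m))) - b[i] * det
            )
            assert res == 0, f"nonzero residual for {subset[i].label}"
        return LumpFractions(lp, eta, subset)
    raise NonBackTranslatableError(
        f"lump {lp.name!r}: no symbolically nonsingular relation subset"
    )


def solve_all(
    network: ReactionNetwork,
    part: FastSlowPartition,
    scheme: LumpingScheme,
    extra: list[sp.Expr] | None = None,
    sources: tuple[str, ...] = ("lump", "qss", "conservation", "extra"),
    strict: bool = False,
) -> FractionParameterSet:
    """Fraction parameters for every lump: singletons get eta == 1, wider
    lumps are solved from their linear relations.  Lumps with no solvable
    system are recorded as non-back-translatable (reduction may proceed
    without back-translation for them unless ``strict``)."""
    exact = exact_conservations(stoichiometric_matrix(network))
    fps = FractionParameterSet(scheme)
    for lp in scheme.lumps:
        if lp.width == 1:
            fps.solved[lp.name] = LumpFractions(
                lp, {lp.members[0]: sp.Integer(1)}, ()
            )
            continue
        try:
            relset = collect_relations(
                network, part, scheme, lp, extra=extra, sources=sources, exact=exact
            )
            fps.solved[lp.name] = solve_fractions(relset)
        except NonBackTranslatableError as exc:
            if strict:
                raise
            fps.unsolved[lp.name] = str(exc)
    return fps


def fractions_with_constraint(
    network: ReactionNetwork,
    part: FastSlowPartition,
    scheme: LumpingScheme,
    extra: list[sp.Expr],
) -> FractionParameterSet:
    """Fractions from the lump definitions, QSS balances and the supplied
    extra constraints only (conservation rows that duplicate lump
    definitions are left out, so the constraint actually enters the
    solved system)."""
    return solve_all(
        network, part, scheme, extra=extra, sources=("lump", "qss", "extra"),
        strict=True,
    )
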