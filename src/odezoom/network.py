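"""Reaction networks in state-space form ``xdot = S @ r(x, p)``.

A :class:`ReactionNetwork` holds an ordered species list with initial
amounts, a positive parameter map, and an ordered reaction list.  Each
reaction contributes one column to the stoichiometric matrix ``S`` and one
rate expression to ``r``.  Reversible reactions written with a single net
rate (e.g. ``k1*S*E - k_1*CS``) are stored as one signed column; reversible
reactions given as a pair of rate constants expand into two irreversible
columns.  Both encodings produce identical right-hand sides.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
import yaml

__all__ = [
    "TIME",
    "Reaction",
    "ReactionNetwork",
    "StoichiometricMatrix",
    "NetworkError",
    "load_network",
    "save_network",
    "parse_reaction",
    "stoichiometric_matrix",
]

#: The independent time variable, usable in rate expressions.
TIME = sp.Symbol("t")

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class NetworkError(ValueError):
    """Raised for malformed networks or model files."""


@dataclass(frozen=True)
class Reaction:
    """A single reaction column: net stoichiometry plus one rate expression."""

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate: sp.Expr
    reversible: bool = False

    def net_stoichiometry(self, species: tuple[str, ...]) -> tuple[int, ...]:
        return tuple(
            self.products.get(s, 0) - self.reactants.get(s, 0) for s in species
        )


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Integer n x q matrix; column j is product-minus-reactant stoichiometry."""

    matrix: sp.ImmutableMatrix
    species: tuple[str, ...]
    reactions: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_numpy(self) -> np.ndarray:
        return np.array(self.matrix.tolist(), dtype=int)

    def column(self, j: int) -> tuple[int, ...]:
        return tuple(int(v) for v in self.matrix.col(j))


class ReactionNetwork:
    """A closed or open biochemical reaction network.

    Parameters
    ----------
    species
        Ordered ``(name, initial_amount)`` pairs; amounts must be >= 0.
    parameters
        Map of parameter name to positive value.
    reactions
        Ordered :class:`Reaction` list (may be empty).
    closed
        True if the network exchanges no matter with the surroundings, in
        which case every exact conservation row annihilates the right-hand
        side along any trajectory.
    """

    def __init__(
        self,
        species: list[tuple[str, float]],
        parameters: dict[str, float],
        reactions: list[Reaction],
        closed: bool = True,
        name: str = "model",
    ) -> None:
        self.name = name
        self.species: tuple[str, ...] = tuple(s for s, _ in species)
        self.initial: dict[str, float] = {s: float(v) for s, v in species}
        self.parameters: dict[str, float] = {k: float(v) for k, v in parameters.items()}
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.closed = bool(closed)
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if len(self.species) < 1:
            raise NetworkError("a network needs at least one species")
        if len(set(self.species)) != len(self.species):
            raise NetworkError("species names must be unique")
        if set(self.species) & set(self.parameters):
            clash = sorted(set(self.species) & set(self.parameters))
            raise NetworkError(f"names used as both species and parameter: {clash}")
        for nm in (*self.species, *self.parameters):
            if not _NAME_RE.match(nm) or nm == "t":
                raise NetworkError(f"invalid name {nm!r}")
        for s, v in self.initial.items():
            if v < 0:
                raise NetworkError(f"negative initial amount for {s}: {v}")
        for k, v in self.parameters.items():
            if v <= 0:
                raise NetworkError(f"parameter {k} must be positive, got {v}")
        allowed = set(self.symbols()) | set(self.parameter_symbols()) | {TIME}
        for rxn in self.reactions:
            for s in (*rxn.reactants, *rxn.products):
                if s not in self.initial:
                    raise NetworkError(f"reaction {rxn.name}: unknown species {s!r}")
            extra = rxn.rate.free_symbols - allowed
            if extra:
                raise NetworkError(
                    f"reaction {rxn.name}: undeclared symbols {sorted(map(str, extra))}"
                )

    # -- symbols -------------------------------------------------------------

    def symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(s) for s in self.species)

    def parameter_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(p) for p in self.parameters)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def index(self, species: str) -> int:
        return self.species.index(species)

    # -- state-space form ----------------------------------------------------

    def rates(self) -> tuple[sp.Expr, ...]:
        """The reaction-rate vector r(x, p) as symbolic expressions."""
        return tuple(r.rate for r in self.reactions)

    def rhs_exprs(self, params: dict[str, float] | None = None) -> tuple[sp.Expr, ...]:
        """Symbolic S @ r, optionally with numeric parameter values substituted."""
        S = stoichiometric_matrix(self).matrix
        r = sp.Matrix(self.rates()) if self.reactions else sp.zeros(0, 1)
        f = S * r if self.reactions else sp.zeros(self.n_species, 1)
        out = tuple(sp.expand(e) for e in f)
        if params is not None:
            subs = {sp.Symbol(k): v for k, v in self.merged_params(params).items()}
            out = tuple(e.subs(subs) for e in out)
        return out

    def merged_params(self, overrides: dict[str, float] | None = None) -> dict[str, float]:
        p = dict(self.parameters)
        for k, v in (overrides or {}).items():
            if k not in p:
                raise NetworkError(f"unknown parameter {k!r}")
            p[k] = float(v)
        return p

    def rhs(
        self,
        x: np.ndarray,
        params: dict[str, float] | None = None,
        t: float = 0.0,
    ) -> np.ndarray:
        """Evaluate S @ r(x, p) at a numeric state."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_species,):
            raise NetworkError(f"state length {x.shape} != n={self.n_species}")
        if np.any(x < 0):
            warnings.warn("negative species amount(s) in rhs evaluation", stacklevel=2)
        return self.rhs_function(params)(t, x)

    def rhs_function(self, params: dict[str, float] | None = None):
        """A ``f(t, x) -> xdot`` callable for use with ODE integrators."""
        p = self.merged_params(params)
        exprs = self.rhs_exprs(p)
        fn = sp.lambdify((TIME, self.symbols()), list(exprs), modules="numpy")
        n = self.n_species

        def f(t, x):
            return np.asarray(fn(t, x), dtype=float).reshape(n)

        return f

    def initial_state(self) -> np.ndarray:
        return np.array([self.initial[s] for s in self.species], dtype=float)

    def with_parameters(self, overrides: dict[str, float]) -> "ReactionNetwork":
        return ReactionNetwork(
            [(s, self.initial[s]) for s in self.species],
            self.merged_params(overrides),
            list(self.reactions),
            closed=self.closed,
            name=self.name,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ReactionNetwork {self.name!r}: {self.n_species} species, "
            f"{self.n_reactions} reactions>"
        )


def stoichiometric_matrix(network: ReactionNetwork) -> StoichiometricMatrix:
    """The integer n x q matrix S with xdot = S @ r."""
    cols = [rxn.net_stoichiometry(network.species) for rxn in network.reactions]
    if cols:
        mat = sp.ImmutableMatrix([[c[i] for c in cols] for i in range(network.n_species)])
    else:
        mat = sp.ImmutableMatrix(network.n_species, 0, [])
    return StoichiometricMatrix(
        matrix=mat,
        species=network.species,
        reactions=tuple(r.name for r in network.reactions),
    )


# -- native model format -----------------------------------------------------

_ARROW_REV = "<->"
_ARROW_IRR = "->"


def _parse_side(side: str, where: str) -> dict[str, int]:
    side = side.strip()
    stoich: dict[str, int] = {}
    if side in ("", "0", "*"):  # empty side: exchange with surroundings
        return stoich
    for term in side.split("+"):
        term = term.strip()
        m = re.match(r"^(\d+)\s+(.*)$", term)
        coeff, name = (int(m.group(1)), m.group(2).strip()) if m else (1, term)
        if not _NAME_RE.match(name):
            raise NetworkError(f"{where}: bad species term {term!r}")
        stoich[name] = stoich.get(name, 0) + coeff
    return stoich


def _parse_expr(text: str, names: set[str], where: str) -> sp.Expr:
    local = {n: sp.Symbol(n) for n in names}
    local["t"] = TIME
    try:
        expr = sp.parse_expr(text, local_dict=local)
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise NetworkError(f"{where}: cannot parse rate {text!r}: {exc}") from exc
    extra = expr.free_symbols - set(local.values())
    if extra:
        raise NetworkError(f"{where}: undeclared symbols {sorted(map(str, extra))}")
    return expr


def _mass_action(k: str, reactants: dict[str, int]) -> sp.Expr:
    expr: sp.Expr = sp.Symbol(k)
    for s, c in reactants.items():
        expr *= sp.Symbol(s) ** c
    return expr


def parse_reaction(
    text: str,
    species: set[str],
    parameters: set[str],
    index: int,
) -> list[Reaction]:
    """Parse one reaction line of the native format.

    ``A + B -> C : k``            mass action with rate constant k
    ``A + B <-> C : kf, kr``      two irreversible mass-action columns
    ``A + B <-> C : k*A*B - q*C`` one signed net-rate column
    ``A -> C : k*A/(K + A)``      one column with an explicit rate law
    """
    where = f"reaction {index + 1} ({text.strip()!r})"
    if ":" not in text:
        raise NetworkError(f"{where}: missing ': rate' part")
    scheme, rate_part = text.split(":", 1)
    if _ARROW_REV in scheme:
        lhs, rhs_side = scheme.split(_ARROW_REV)
        reversible = True
    elif _ARROW_IRR in scheme:
        lhs, rhs_side = scheme.split(_ARROW_IRR)
        reversible = False
    else:
        raise NetworkError(f"{where}: no '->' or '<->' arrow")
    reactants = _parse_side(lhs, where)
    products = _parse_side(rhs_side, where)
    for s in (*reactants, *products):
        if s not in species:
            raise NetworkError(f"{where}: undeclared species {s!r}")

    parts = [p.strip() for p in rate_part.split(",")]
    base = f"r{index + 1}"
    if len(parts) == 2 and all(p in parameters for p in parts):
        if not reversible:
            raise NetworkError(f"{where}: two rate constants given for an '->' reaction")
        kf, kr = parts
        return [
            Reaction(base + "f", reactants, products, _mass_action(kf, reactants), False),
            Reaction(base + "b", products, reactants, _mass_action(kr, products), False),
        ]
    if len(parts) != 1:
        raise NetworkError(f"{where}: expected one rate expression or two constants")
    (rate_text,) = parts
    if rate_text in parameters:
        if reversible:
            raise NetworkError(
                f"{where}: a '<->' reaction needs two constants or a net-rate expression"
            )
        return [Reaction(base, reactants, products, _mass_action(rate_text, reactants), False)]
    rate = _parse_expr(rate_text, species | parameters, where)
    return [Reaction(base, reactants, products, rate, reversible)]


def network_from_dict(doc: dict, name: str = "model") -> ReactionNetwork:
    """Build a network from a parsed native-format mapping."""
    if not isinstance(doc, dict) or "species" not in doc:
        raise NetworkError("model file must be a mapping with a 'species' section")
    species = [(str(k), float(v)) for k, v in doc["species"].items()]
    parameters = {str(k): float(v) for k, v in (doc.get("parameters") or {}).items()}
    sp_names = {s for s, _ in species}
    reactions: list[Reaction] = []
    for i, line in enumerate(doc.get("reactions") or []):
        reactions.extend(parse_reaction(str(line), sp_names, set(parameters), i))
    return ReactionNetwork(
        species,
        parameters,
        reactions,
        closed=bool(doc.get("closed", True)),
        name=str(doc.get("name", name)),
    )


def load_network(path: str, format: str = "native") -> ReactionNetwork:
    """Read a model file; species/reaction order equals file order."""
    if format == "native":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return network_from_dict(doc, name=str(path))
    if format == "sbml":
        from .sbml import read_sbml

        return read_sbml(path)
    raise NetworkError(f"unknown format {format!r}")


def _format_reaction(rxn: Reaction) -> str:
    def side(st: dict[str, int]) -> str:
        if not st:
            return "*"
        return " + ".join(s if c == 1 else f"{c} {s}" for s, c in st.items())

    arrow = _ARROW_REV if rxn.reversible else _ARROW_IRR
    return f"{side(rxn.reactants)} {arrow} {side(rxn.products)} : {rxn.rate}"


def save_network(network: ReactionNetwork, path: str) -> None:
    """Write the native YAML format (round-trips to an identical rhs)."""
    doc = {
        "name": network.name,
        "closed": network.closed,
        "species": {s: network.initial[s] for s in network.species},
        "parameters": dict(network.parameters),
        "reactions": [_format_reaction(r) for r in network.reactions],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)
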