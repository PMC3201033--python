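"""Built-in case-study models, the closed-form oracle for the small binding
example, and a seeded random generator of fast-cluster networks.

The enzyme-kinetics model ships with the printed rate constants and initial
conditions.  The glucose-transport model ships with the printed structure
(species, reactions, conservations); its parameter values are synthetic
placeholders satisfying the fast/slow separation, since the source study
does not print them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import sympy as sp

from .conservation import (
    ConservationBasis,
    FastSlowPartition,
    apparent_conservations,
    exact_conservations,
    partition,
)
from .lumping import LumpingScheme, build_scheme
from .network import (
    NetworkError,
    ReactionNetwork,
    network_from_dict,
    stoichiometric_matrix,
)

__all__ = [
    "FixtureModel",
    "enzyme_kinetics",
    "glucose_transport",
    "small_example",
    "oracle_backtranslate",
    "random_fast_cluster",
    "builtin_model",
]


@dataclass
class FixtureModel:
    """A network bundled with its recommended reduction ingredients."""

    network: ReactionNetwork
    fast_reactions: tuple[int, ...]
    exact: ConservationBasis
    apparent: ConservationBasis
    partition: FastSlowPartition
    schemes: dict[str, LumpingScheme] = field(default_factory=dict)
    extra_constraints: dict[str, list[sp.Expr]] = field(default_factory=dict)
    naive_config: dict = field(default_factory=dict)
    notes: str = ""


def _load_builtin(name: str) -> ReactionNetwork:
    text = resources.files("odezoom.models").joinpath(f"{name}.yaml").read_text()
    import yaml

    return network_from_dict(yaml.safe_load(text), name=name)


def _rename_by_members(basis: ConservationBasis, naming: dict[str, tuple[str, ...]]) -> ConservationBasis:
    """Rename basis rows by matching their (unit-coefficient) supports."""
    mapping = {}
    for i, auto in enumerate(basis.names):
        support = tuple(
            s for s, v in zip(basis.species, basis.row(i)) if v
        )
        for wanted, members in naming.items():
            if set(members) == set(support):
                mapping[auto] = wanted
                break
    return basis.rename(mapping)


def enzyme_kinetics() -> FixtureModel:
    """The five-species enzyme model with the printed constants.

    Fast channels: substrate binding (r1) and product binding (r3); the
    catalytic conversion r2 is slow.  Recommended schemes: ``two_state``
    (states S, P; total enzyme LE retained as a constant) and the further
    one-state reduction obtained by eliminating P through the substrate
    total LT (see :func:`odezoom.reduction.eliminate_state`).
    """
    net = _load_builtin("enzyme")
    part = partition(net, [0, 2])
    exact = _rename_by_members(
        exact_conservations(stoichiometric_matrix(net)),
        {"LE": ("E", "CS", "CP"), "LT": ("S", "P", "CS", "CP")},
    )
    apparent = _rename_by_members(
        apparent_conservations(part),
        {"LS": ("S", "CS"), "LP": ("P", "CP"), "LE": ("E", "CS", "CP")},
    )
    schemes = {"two_state": build_scheme(apparent, exact, keep=["LE"])}
    return FixtureModel(
        network=net,
        fast_reactions=(0, 2),
        exact=exact,
        apparent=apparent,
        partition=part,
        schemes=schemes,
        notes=(
            "rate constants and initial conditions as printed; derived "
            "constants M1 = k1/k_1 = 0.5, M3 = k3/k_3 = 3, LE = 1"
        ),
    )


def glucose_transport(params: dict[str, float] | None = None) -> FixtureModel:
    """The nine-species glucose-transport model.

    Fast: the four carrier binding channels (8 irreversible columns);
    slow: carrier translocation (alpha) and free-carrier exchange (beta).
    Parameter values are synthetic placeholders (documented in the model
    file); every structural property (conservations, clusters, scheme state
    counts) is parameter free.

    Shipped schemes: ``four_state`` (keep LE1 and the exact LG6P; the inner
    carriers lump into LE3), ``five_state`` (keep LE1 and LE2; G6P stays an
    explicit state), ``three_state_constrained`` (keep the full exact
    carrier conservation LE, back-translated with the constant-regional-
    transporter constraint).
    """
    net = _load_builtin("glucose")
    if params:
        net = net.with_parameters(params)
    part = partition(net, range(8))
    exact = _rename_by_members(
        exact_conservations(stoichiometric_matrix(net)),
        {
            "LG6P": ("E_G6Pi", "E_Glc_G6Pi", "G6Pi"),
            "LGlc": ("Glce", "Glci", "E_Glc_G6Pi", "E_Glce", "E_Glci"),
            "LE": ("E_G6Pi", "E_Glc_G6Pi", "E_Glce", "E_Glci", "Ee", "Ei"),
        },
    )
    apparent = _rename_by_members(
        apparent_conservations(part),
        {
            "LE1": ("E_Glce", "Ee"),
            "LGlc1": ("Glce", "E_Glce"),
            "LG6P": ("E_G6Pi", "E_Glc_G6Pi", "G6Pi"),
            "LGlc2": ("Glci", "E_Glc_G6Pi", "E_Glci"),
            "LE2": ("E_G6Pi", "E_Glc_G6Pi", "E_Glci", "Ei"),
        },
    )
    schemes = {
        "four_state": build_scheme(
            apparent, exact, keep=["LE1", "LG6P"],
            assignment={"LE3": ["E_Glci", "Ei"]},
        ),
        "five_state": build_scheme(apparent, exact, keep=["LE1", "LE2"]),
        "three_state_constrained": build_scheme(apparent, exact, keep=["LE"]),
    }
    alpha, beta = sp.Symbol("alpha"), sp.Symbol("beta")
    eGlce, eGlci, Ee, Ei = sp.symbols("E_Glce E_Glci Ee Ei")
    constraint = alpha * (eGlce - eGlci) + beta * (Ee - Ei)
    return FixtureModel(
        network=net,
        fast_reactions=tuple(range(8)),
        exact=exact,
        apparent=apparent,
        partition=part,
        schemes=schemes,
        extra_constraints={"three_state_constrained": [constraint]},
        naive_config={
            "qss_species": ["Glce", "Glci", "E_G6Pi", "E_Glc_G6Pi"],
            "conservation_eliminate": {"G6Pi": "LG6P"},
        },
        notes="structure as printed; parameter values are placeholders",
    )


def small_example(
    k1: float = 1000.0,
    k_minus1: float = 2000.0,
    slow_flows: list[str] | None = None,
    v_in: float = 0.5,
    k_out: float = 1.0,
    a0: float = 1.0,
    b0: float = 1.0,
    c0: float = 0.0,
) -> FixtureModel:
    """The fast reversible binding A + B <-> C embedded in slow flows.

    By default a constant inflow feeds A and a first-order outflow drains C
    (the surrounding slow network); pass ``slow_flows=[]`` for the closed
    cluster.  The recommended scheme keeps the apparent moiety L1 = A + C;
    B becomes a singleton state, reproducing the two-state reduced form
    with the scalar correction factor.
    """
    if k1 <= 0 or k_minus1 <= 0:
        raise NetworkError("rate constants must be positive")
    if slow_flows is None:
        slow_flows = ["* -> A : v_in", f"C -> * : k_out*C"]
    doc = {
        "name": "small_example",
        "closed": not slow_flows,
        "species": {"A": a0, "B": b0, "C": c0},
        "parameters": {
            "k1": k1,
            "k_1": k_minus1,
            **({"v_in": v_in, "k_out": k_out} if slow_flows else {}),
        },
        "reactions": ["A + B <-> C : k1*A*B - k_1*C", *slow_flows],
    }
    net = network_from_dict(doc)
    part = partition(net, [0])
    exact = exact_conservations(stoichiometric_matrix(net))
    apparent = _rename_by_members(
        apparent_conservations(part), {"L1": ("A", "C"), "L2": ("B", "C")}
    )
    schemes = {"two_state": build_scheme(apparent, exact, keep=["L1"])}
    return FixtureModel(
        network=net,
        fast_reactions=(0,),
        exact=exact,
        apparent=apparent,
        partition=part,
        schemes=schemes,
        notes="closed-form quadratic back-translation available as oracle",
    )


def oracle_backtranslate(L1: float, L2: float, K1: float) -> tuple[float, float, float]:
    """Closed-form nonnegative solution of the binding equilibrium
    {A*B = K1*C, A + C = L1, B + C = L2} for (A, B, C)."""
    disc = (L1 + L2 + K1) ** 2 - 4 * L1 * L2
    root = math.sqrt(disc)
    A = 0.5 * (L1 - L2 - K1 + root)
    B = 0.5 * (-L1 + L2 - K1 + root)
    C = 0.5 * (L1 + L2 + K1 - root)
    return A, B, C


def random_fast_cluster(
    seed: int,
    n_clusters: int = 1,
    n_slow: int = 1,
    separation: float = 1e4,
) -> FixtureModel:
    """A seeded random closed mass-action network with designated fast
    reversible binding clusters.

    Each cluster contributes A + B <-> C with rates of scale ``separation``
    and a slow recycling chain C -> P1 -> ... -> Pn -> A + B with rates of
    scale 1, so the network is closed (mass conserved) and each cluster
    carries two apparent conservation relations by construction.
    """
    if separation < 1:
        raise NetworkError("separation must be >= 1")
    rng = np.random.default_rng(seed)
    species: dict[str, float] = {}
    parameters: dict[str, float] = {}
    reactions: list[str] = []
    fast_idx: list[int] = []
    col = 0
    for c in range(n_clusters):
        A, B, C = f"A{c}", f"B{c}", f"C{c}"
        species[A] = float(rng.uniform(0.5, 1.5))
        species[B] = float(rng.uniform(0.5, 1.5))
        species[C] = 0.0
        kf, kr = f"kf{c}", f"kr{c}"
        parameters[kf] = separation * float(rng.uniform(0.5, 2.0))
        parameters[kr] = separation * float(rng.uniform(0.5, 2.0))
        reactions.append(f"{A} + {B} <-> {C} : {kf}*{A}*{B} - {kr}*{C}")
        fast_idx.append(col)
        col += 1
        chain = [C] + [f"P{c}_{j}" for j in range(n_slow)]
        for s in chain[1:]:
            species[s] = 0.0
        for a, b in zip(chain, chain[1:]):
            k = f"s{c}_{len(reactions)}"
            parameters[k] = float(rng.uniform(0.5, 2.0))
            reactions.append(f"{a} -> {b} : {k}")
            col += 1
        k = f"s{c}_{len(reactions)}"
        parameters[k] = float(rng.uniform(0.5, 2.0))
        reactions.append(f"{chain[-1]} -> {A} + {B} : {k}")
        col += 1
    net = network_from_dict(
        {
            "name": f"random_cluster_{seed}",
            "closed": True,
            "species": species,
            "parameters": parameters,
            "reactions": reactions,
        }
    )
    part = partition(net, fast_idx)
    exact = exact_conservations(stoichiometric_matrix(net))
    apparent = apparent_conservations(part)
    schemes = {}
    return FixtureModel(
        network=net,
        fast_reactions=tuple(fast_idx),
        exact=exact,
        apparent=apparent,
        partition=part,
        schemes=schemes,
        notes="seeded synthetic network",
    )


def builtin_model(name: str) -> FixtureModel:
    """Resolve ``enzyme`` / ``glucose`` / ``small`` fixture names."""
    if name == "enzyme":
        return enzyme_kinetics()
    if name == "glucose":
        return glucose_transport()
    if name in ("small", "small_example"):
        return small_example()
    raise NetworkError(f"unknown builtin model {name!r}")
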