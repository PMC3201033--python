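"""Conserved-moiety analysis and the fast/slow reaction split.

Exact conserved moieties are integer left null vectors of the full
stoichiometric matrix ``S``; apparent conservations are left null vectors
of the fast-subnetwork matrix ``S_f`` and are only conserved on the fast
time scale.  All null spaces are computed in exact rational arithmetic and
scaled to coprime integers; a nonnegative basis is searched for with a
tableau (double-description) pass over the cone ``{m >= 0 : m S = 0}``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import sympy as sp

from .network import NetworkError, ReactionNetwork, StoichiometricMatrix, stoichiometric_matrix

__all__ = [
    "ConservationBasis",
    "FastSlowPartition",
    "FastCluster",
    "exact_conservations",
    "apparent_conservations",
    "partition",
    "maximize_vanishing_rows",
    "fast_clusters",
    "suggest_fast_reactions",
]


@dataclass(frozen=True)
class ConservationBasis:
    """Integer rows annihilating a stoichiometric matrix (``rows @ S == 0``)."""

    rows: sp.ImmutableMatrix  # a x m, integer entries
    species: tuple[str, ...]  # column labels
    names: tuple[str, ...]  # row labels
    target: str  # "S" (exact) or "S_f" (apparent)
    nonnegative: bool

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def row(self, i: int) -> tuple[int, ...]:
        return tuple(int(v) for v in self.rows.row(i))

    def row_by_name(self, name: str) -> tuple[int, ...]:
        return self.row(self.names.index(name))

    def rename(self, mapping: dict[str, str]) -> "ConservationBasis":
        return replace(self, names=tuple(mapping.get(n, n) for n in self.names))

    def values(self, state: dict[str, float]) -> dict[str, float]:
        """Evaluate each conserved sum at a numeric state."""
        out = {}
        for i, nm in enumerate(self.names):
            out[nm] = float(sum(c * state[s] for c, s in zip(self.row(i), self.species)))
        return out

    def expressions(self) -> dict[str, sp.Expr]:
        syms = [sp.Symbol(s) for s in self.species]
        return {
            nm: sp.Add(*(c * x for c, x in zip(self.row(i), syms)))
            for i, nm in enumerate(self.names)
        }

    def verify(self, S: sp.ImmutableMatrix) -> bool:
        """Exact integer check of rows @ S == 0."""
        return (self.rows * sp.Matrix(S)).is_zero_matrix


@dataclass(frozen=True)
class FastCluster:
    species: tuple[str, ...]
    reactions: tuple[int, ...]


@dataclass(frozen=True)
class FastSlowPartition:
    """The split xdot_f = S_s r_s(x, p) + S_f r_f(x_f, p) over the fast species."""

    network: ReactionNetwork
    fast_reactions: tuple[int, ...]
    slow_reactions: tuple[int, ...]
    fast_species: tuple[str, ...]
    Sf: sp.ImmutableMatrix  # n_f x q_f
    Ss: sp.ImmutableMatrix  # n_f x q_s
    window: tuple[float, float] = (0.0, math.inf)  # validity [T0, T1); metadata only

    @property
    def rf(self) -> tuple[sp.Expr, ...]:
        return tuple(self.network.reactions[j].rate for j in self.fast_reactions)

    @property
    def rs(self) -> tuple[sp.Expr, ...]:
        return tuple(self.network.reactions[j].rate for j in self.slow_reactions)

    def fast_index(self, name: str) -> int:
        return self.fast_species.index(name)

    def balance_equations(self) -> list[sp.Expr]:
        """One net-rate expression per fast reaction channel, ~0 at QSS.

        Irreversible column pairs that are exact structural reverses of each
        other are merged into a single forward-minus-backward balance.
        """
        S = stoichiometric_matrix(self.network).matrix
        used: set[int] = set()
        eqs: list[sp.Expr] = []
        fast = list(self.fast_reactions)
        for a_pos, j in enumerate(fast):
            if j in used:
                continue
            mate = None
            for k in fast[a_pos + 1 :]:
                if k not in used and S.col(k) == -S.col(j):
                    mate = k
                    break
            if mate is not None:
                eqs.append(sp.expand(self.network.reactions[j].rate - self.network.reactions[mate].rate))
                used.update((j, mate))
            else:
                eqs.append(sp.expand(self.network.reactions[j].rate))
                used.add(j)
        return eqs


def _integer_scale(vec: list[sp.Rational]) -> tuple[int, ...]:
    denoms = [sp.Rational(v).q for v in vec]
    lcm = math.lcm(*denoms) if denoms else 1
    ints = [int(v * lcm) for v in vec]
    g = math.gcd(*(abs(i) for i in ints)) if any(ints) else 1
    return tuple(i // g for i in ints)


def _rational_left_nullspace(S: sp.Matrix) -> list[tuple[int, ...]]:
    """Integer-scaled basis of {m : m S = 0}, exact arithmetic."""
    return [_integer_scale(list(v)) for v in S.T.nullspace()]


_TABLEAU_CAP = 1024


def _nonnegative_rays(S: sp.Matrix) -> list[tuple[int, ...]]:
    """Extreme rays of {m >= 0 : m S = 0} by the tableau method (exact)."""
    n, q = S.shape
    rows: list[tuple[tuple[sp.Rational, ...], tuple[sp.Rational, ...]]] = [
        (tuple(S.row(i)), tuple(sp.Integer(1) if k == i else sp.Integer(0) for k in range(n)))
        for i in range(n)
    ]
    for j in range(q):
        keep = [r for r in rows if r[0][j] == 0]
        pos = [r for r in rows if r[0][j] > 0]
        neg = [r for r in rows if r[0][j] < 0]
        if len(keep) + len(pos) * len(neg) > _TABLEAU_CAP:
            raise OverflowError("tableau growth exceeded cap")
        for rp, rn in itertools.product(pos, neg):
            a, b = rp[0][j], -rn[0][j]
            left = tuple(b * x + a * y for x, y in zip(rp[0], rn[0]))
            right = tuple(b * x + a * y for x, y in zip(rp[1], rn[1]))
            keep.append((left, right))
        rows = keep
    rays = []
    seen = set()
    for _, right in rows:
        vec = _integer_scale(list(right))
        if any(vec) and vec not in seen:
            seen.add(vec)
            rays.append(vec)
    # drop rays whose support strictly contains another ray's support
    supports = [frozenset(i for i, v in enumerate(r) if v) for r in rays]
    minimal = [
        r
        for r, s in zip(rays, supports)
        if not any(o < s for o in supports)
    ]
    return sorted(minimal, key=lambda r: (sum(1 for v in r if v), r))


def _left_null_basis(S: sp.Matrix, species: tuple[str, ...], target: str) -> ConservationBasis:
    a = S.shape[0] - S.rank()
    if a == 0:
        return ConservationBasis(
            sp.ImmutableMatrix(0, len(species), []), species, (), target, True
        )
    chosen: list[tuple[int, ...]] = []
    nonneg = True
    try:
        rays = _nonnegative_rays(S)
    except OverflowError:
        rays = []
    cur = sp.zeros(0, len(species))
    for ray in rays:
        cand = cur.col_join(sp.Matrix([list(ray)]))
        if cand.rank() > cur.rank():
            cur = cand
            chosen.append(ray)
        if len(chosen) == a:
            break
    if len(chosen) < a:
        nonneg = False
        warnings.warn(
            "no full nonnegative conservation basis found; falling back to a "
            "signed integer basis",
            stacklevel=2,
        )
        for vec in _rational_left_nullspace(S):
            cand = cur.col_join(sp.Matrix([list(vec)]))
            if cand.rank() > cur.rank():
                cur = cand
                chosen.append(vec)
            if len(chosen) == a:
                break
    names = tuple(f"L{i + 1}" for i in range(len(chosen)))
    basis = ConservationBasis(
        sp.ImmutableMatrix([list(r) for r in chosen]), species, names, target, nonneg
    )
    assert basis.verify(S)
    return basis


def exact_conservations(S: StoichiometricMatrix) -> ConservationBasis:
    """Basis of exact conserved moieties: integer rows with rows @ S == 0."""
    return _left_null_basis(sp.Matrix(S.matrix), S.species, "S")


def partition(
    network: ReactionNetwork,
    fast_reactions: set[int] | list[int],
    fast_species: list[str] | str = "auto",
) -> FastSlowPartition:
    """Split reactions into fast/slow and restrict both to the fast species."""
    fast = tuple(sorted(set(int(j) for j in fast_reactions)))
    for j in fast:
        if not 0 <= j < network.n_reactions:
            raise NetworkError(f"fast reaction index {j} out of range")
    slow = tuple(j for j in range(network.n_reactions) if j not in fast)
    S = stoichiometric_matrix(network).matrix

    touched = [
        s
        for i, s in enumerate(network.species)
        if any(S[i, j] != 0 for j in fast)
    ]
    if fast_species == "auto":
        xf = tuple(touched)
    else:
        xf = tuple(fast_species)
        orphans = sorted(set(xf) - set(touched))
        if orphans:
            raise NetworkError(
                f"declared fast species touched by no fast reaction: {orphans}"
            )
    rows = [network.index(s) for s in xf]
    Sf = sp.ImmutableMatrix([[S[i, j] for j in fast] for i in rows]) if fast else sp.ImmutableMatrix(len(rows), 0, [])
    Ss = sp.ImmutableMatrix([[S[i, j] for j in slow] for i in rows]) if slow else sp.ImmutableMatrix(len(rows), 0, [])
    return FastSlowPartition(network, fast, slow, xf, Sf, Ss)


def apparent_conservations(part: FastSlowPartition) -> ConservationBasis:
    """Basis of the left null space of S_f: the apparent conserved moieties."""
    return _left_null_basis(sp.Matrix(part.Sf), part.fast_species, "S_f")


def maximize_vanishing_rows(
    basis: ConservationBasis, Ss: sp.Matrix
) -> ConservationBasis:
    """Transform the basis with a nonsingular N so M_hat = N M has a maximal
    number of rows annihilating ``Ss`` (those lumps are constant under the
    slow reactions too).  The vanishing-row count equals a - rank(M @ Ss)."""
    M = sp.Matrix(basis.rows)
    a = M.shape[0]
    B = M * sp.Matrix(Ss)
    null = [_integer_scale(list(v)) for v in B.T.nullspace()]
    N = sp.Matrix(0, a, [])
    names: list[str] = []
    for vec in null:
        N = N.col_join(sp.Matrix([list(vec)]))
        terms = [
            (c, basis.names[i]) for i, c in enumerate(vec) if c
        ]
        if len(terms) == 1 and terms[0][0] == 1:
            names.append(terms[0][1])
        else:
            names.append("+".join(f"{'' if c == 1 else c}{nm}" for c, nm in terms))
    for i in range(a):
        e = sp.Matrix([[1 if k == i else 0 for k in range(a)]])
        cand = N.col_join(e)
        if cand.rank() > N.rank():
            N = cand
            names.append(basis.names[i])
    Mhat = N * M
    nonneg = all(v >= 0 for v in Mhat)
    out = ConservationBasis(
        sp.ImmutableMatrix(Mhat), basis.species, tuple(names), basis.target, nonneg
    )
    assert (sp.Matrix(out.rows) * sp.Matrix(Ss)).rank() == B.rank()
    return out


def count_vanishing_rows(basis: ConservationBasis, Ss: sp.Matrix) -> int:
    B = sp.Matrix(basis.rows) * sp.Matrix(Ss)
    return sum(1 for i in range(B.shape[0]) if all(v == 0 for v in B.row(i)))


def fast_clusters(part: FastSlowPartition) -> list[FastCluster]:
    """Connected components of the bipartite fast species / fast reaction graph."""
    g = nx.Graph()
    for s in part.fast_species:
        g.add_node(("s", s))
    for j in part.fast_reactions:
        g.add_node(("r", j))
        rxn = part.network.reactions[j]
        for s in (*rxn.reactants, *rxn.products):
            if s in part.fast_species:
                g.add_edge(("r", j), ("s", s))
    clusters = []
    order = {s: i for i, s in enumerate(part.fast_species)}
    for comp in nx.connected_components(g):
        species = tuple(sorted((n for k, n in comp if k == "s"), key=order.get))
        reactions = tuple(sorted(n for k, n in comp if k == "r"))
        if species:
            clusters.append(FastCluster(species, reactions))
    clusters.sort(key=lambda c: order[c.species[0]])
    return clusters


def suggest_fast_reactions(
    network: ReactionNetwork,
    t_pilot: float,
    threshold: float = 1e-2,
    n_samples: int = 50,
) -> list[int]:
    """Flux-balance heuristic: channels whose forward and backward rates
    stay approximately equal along a pilot simulation (median net/gross
    flux ratio below the threshold, sampled after the initial transient).
    Irreversible column pairs that are structural reverses are treated as
    one channel and both indices reported.  Advisory only -- the fast set
    is always explicit user input to the reduction itself."""
    from scipy.integrate import solve_ivp

    t_eval = np.linspace(t_pilot / 10, t_pilot, n_samples)
    sol = solve_ivp(
        network.rhs_function(),
        (0.0, t_pilot),
        network.initial_state(),
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
        t_eval=t_eval,
    )
    syms = network.symbols()
    S = stoichiometric_matrix(network).matrix
    psubs = {sp.Symbol(k): v for k, v in network.parameters.items()}

    # group structural reverse pairs into channels
    channels: list[tuple[list[int], sp.Expr]] = []
    used: set[int] = set()
    for j, rxn in enumerate(network.reactions):
        if j in used:
            continue
        mate = next(
            (
                k
                for k in range(j + 1, network.n_reactions)
                if k not in used and S.col(k) == -S.col(j)
            ),
            None,
        )
        if mate is not None:
            used.update((j, mate))
            net = rxn.rate - network.reactions[mate].rate
        else:
            used.add(j)
            net = rxn.rate
        channels.append(([j] if mate is None else [j, mate], net))

    fast: list[int] = []
    for idx, net in channels:
        net = sp.expand(net.subs(psubs))
        gross = sp.Add(*(sp.Abs(term) for term in sp.Add.make_args(net)))
        f_net = sp.lambdify((syms,), net, modules="numpy")
        f_gross = sp.lambdify((syms,), gross, modules="numpy")
        nets = np.array([abs(float(f_net(sol.y[:, k]))) for k in range(n_samples)])
        grosses = np.array([float(f_gross(sol.y[:, k])) for k in range(n_samples)])
        mask = grosses > 1e-12
        if mask.any() and np.median(nets[mask] / grosses[mask]) < threshold:
            fast.extend(idx)
    return sorted(fast)
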