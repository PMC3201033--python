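"""Reduced-model derivation (Jacobian-corrected lump dynamics) and simulation.

The dynamics of the modified lumped state variables is

    lm_dot = (I + J(lm, p))^-1  M S_s r_s(g(lm, p), p)

where ``M`` stacks the parent conservation rows of the lumps, ``g`` maps
each fast species to its fraction-parameter expression, and
``J_ij = sum_k (M_ik - Mm_ik) dg_k/dlm_j``.  The correction is block
diagonal over the fast clusters; blocks of dimension <= 4 are inverted
symbolically, larger ones are solved numerically at each evaluation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .conservation import (
    ConservationBasis,
    FastSlowPartition,
    apparent_conservations,
    fast_clusters,
    exact_conservations,
)
from .fractions import FractionParameterSet, solve_all
from .lumping import LumpingScheme
from .network import NetworkError, ReactionNetwork, TIME, stoichiometric_matrix

__all__ = [
    "ReducedModel",
    "Trajectory",
    "ReductionError",
    "jacobian_correction",
    "derive_reduced",
    "naive_reduce",
    "reduced_initial_conditions",
    "simulate",
    "eliminate_state",
    "count_parameters",
]

SYMBOLIC_INVERSE_MAX = 4
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class ReductionError(NetworkError):
    """Raised when the reduced dynamics cannot be derived or evaluated."""


@dataclass(frozen=True)
class Trajectory:
    """Time grid (strictly increasing) and per-state sample columns."""

    t: np.ndarray
    values: dict[str, np.ndarray]
    model_id: str = ""
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ReductionError("time grid must be strictly increasing")
        for nm, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ReductionError(f"non-finite values in trajectory of {nm}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def array(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = names or self.names
        return np.column_stack([self.values[n] for n in names])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, **self.values})


@dataclass
class ClusterBlock:
    """One fast-cluster block of the (I+J) correction."""

    lump_names: tuple[str, ...]  # dynamic lumps in this block
    J: sp.Matrix  # symbolic block of J over the dynamic lumps
    ldot: sp.Matrix  # parent-lump balance rates M S_s r_s (g-substituted)
    symbolic: bool  # inverted symbolically or solved numerically


@dataclass
class ReducedModel:
    """The reduced system plus everything needed for back-translation."""

    network: ReactionNetwork
    partition: FastSlowPartition
    scheme: LumpingScheme
    fractions: FractionParameterSet
    states: tuple[str, ...]  # dynamic lumps then pass-through slow species
    rhs: dict[str, sp.Expr]  # closed-form rhs (symbolic blocks only)
    constants: dict[str, float]  # retained exact conservations
    blocks: tuple[ClusterBlock, ...]
    g: dict[str, sp.Expr] = field(default_factory=dict)  # composed back-translation
    name: str = "reduced"

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(s) for s in self.states)

    def parameter_values(self, overrides: dict[str, float] | None = None) -> dict[str, float]:
        return self.network.merged_params(overrides)

    def _subs_numeric(self, overrides: dict[str, float] | None) -> dict[sp.Symbol, float]:
        subs = {sp.Symbol(k): v for k, v in self.parameter_values(overrides).items()}
        subs.update({sp.Symbol(k): v for k, v in self.constants.items()})
        return subs

    def rhs_function(self, params: dict[str, float] | None = None):
        """``f(t, y) -> ydot`` over ``self.states``."""
        subs = self._subs_numeric(params)
        syms = self.state_symbols()
        if all(b.symbolic for b in self.blocks):
            exprs = [self.rhs[s].subs(subs) for s in self.states]
            fn = sp.lambdify((TIME, syms), exprs, modules="numpy")
            n = self.n_states

            def f(t, y):
                return np.asarray(fn(t, y), dtype=float).reshape(n)

            return f

        # mixed path: numeric linear solve for oversized blocks
        pieces = []
        for b in self.blocks:
            idx = [self.states.index(nm) for nm in b.lump_names]
            if b.symbolic:
                exprs = [self.rhs[nm].subs(subs) for nm in b.lump_names]
                fn = sp.lambdify((TIME, syms), exprs, modules="numpy")
                pieces.append(("direct", idx, fn))
            else:
                Jf = sp.lambdify((TIME, syms), b.J.subs(subs).tolist(), modules="numpy")
                lf = sp.lambdify(
                    (TIME, syms), [e.subs(subs) for e in b.ldot], modules="numpy"
                )
                pieces.append(("solve", idx, (Jf, lf)))
        slow = [
            (self.states.index(nm), self.rhs[nm].subs(subs))
            for nm in self.states
            if not any(nm in b.lump_names for b in self.blocks)
        ]
        slow_fn = (
            sp.lambdify((TIME, syms), [e for _, e in slow], modules="numpy")
            if slow
            else None
        )
        n = self.n_states

        def f(t, y):
            out = np.zeros(n)
            for kind, idx, payload in pieces:
                if kind == "direct":
                    out[idx] = np.asarray(payload(t, y), dtype=float)
                else:
                    Jf, lf = payload
                    A = np.eye(len(idx)) + np.asarray(Jf(t, y), dtype=float)
                    det = np.linalg.det(A)
                    if det == 0:
                        raise ReductionError(
                            f"singular I+J at t={t}, state={dict(zip(self.states, y))}"
                        )
                    out[idx] = np.linalg.solve(A, np.asarray(lf(t, y), dtype=float))
            if slow_fn is not None:
                vals = np.asarray(slow_fn(t, y), dtype=float)
                for (i, _), v in zip(slow, vals):
                    out[i] = v
            return out

        return f

    def default_initial_state(self) -> dict[str, float]:
        """M_m applied to the original initial condition (no equilibration)."""
        x0 = dict(zip(self.network.species, self.network.initial_state()))
        lm0 = self.scheme.apply(x0)
        out = {s: lm0[s] if s in lm0 else x0[s] for s in self.states}
        return out

    def det_correction(self, state: dict[str, float], params=None) -> dict[str, float]:
        """det(I+J) per symbolic block at a numeric reduced state."""
        subs = self._subs_numeric(params)
        subs.update({sp.Symbol(k): v for k, v in state.items()})
        out = {}
        for b in self.blocks:
            A = sp.eye(b.J.shape[0]) + b.J
            out["+".join(b.lump_names)] = float(A.subs(subs).det())
        return out


def _solve_linear_block(A: sp.Matrix, b: sp.Matrix) -> list[sp.Expr]:
    """Solve A x = b with rational-function entries by clearing denominators
    row-wise and using the adjugate; avoids the GCD blow-up of a direct
    LU solve on nested rational functions."""
    n = A.shape[0]
    A2 = sp.zeros(n, n)
    b2 = sp.zeros(n, 1)
    for i in range(n):
        entries = [sp.cancel(A[i, j]) for j in range(n)] + [sp.cancel(b[i])]
        lc = sp.lcm([sp.fraction(e)[1] for e in entries])
        for j in range(n):
            A2[i, j] = sp.expand(sp.cancel(entries[j] * lc))
        b2[i] = sp.expand(sp.cancel(entries[n] * lc))
    det = sp.expand(A2.det(method="berkowitz"))
    if det == 0:
        raise ReductionError("singular I+J correction (symbolic determinant 0)")
    num = A2.adjugate() * b2
    out = []
    for i in range(n):
        e = sp.expand(num[i])
        # final GCD cleanup only while it stays cheap; large quotients are
        # left as num/det (equivalent, and lambdify does not care)
        if sp.count_ops(e) + sp.count_ops(det) < 4000:
            out.append(sp.cancel(e / det))
        else:
            out.append(e / det)
    return out


def _cluster_of(lump, clusters) -> set[int]:
    return {
        ci
        for ci, cl in enumerate(clusters)
        for m in lump.members
        if m in cl.species
    }


def jacobian_correction(
    scheme: LumpingScheme,
    fractions: FractionParameterSet,
    g: dict[str, sp.Expr] | None = None,
) -> sp.Matrix:
    """The full J with J_ij = sum_k (M_ik - Mm_ik) dg_k/dlm_j over all lumps."""
    if g is None:
        g = fractions.g()
    lumps = scheme.lumps
    b = len(lumps)
    J = sp.zeros(b, b)
    for i, lp in enumerate(lumps):
        diff_vec = {
            s: lp.parent[k] - (1 if s in lp.members else 0)
            for k, s in enumerate(scheme.fast_species)
        }
        expr = sp.Integer(0)
        for s, c in diff_vec.items():
            if c == 0:
                continue
            if s not in g:
                raise ReductionError(
                    f"species {s!r} in the correction support of lump "
                    f"{lp.name!r} has no back-translation g"
                )
            expr += c * g[s]
        for j, lq in enumerate(lumps):
            J[i, j] = sp.cancel(sp.diff(expr, sp.Symbol(lq.name)))
    return J


def derive_reduced(
    network: ReactionNetwork,
    part: FastSlowPartition,
    scheme: LumpingScheme,
    fractions: FractionParameterSet | None = None,
    extra: list[sp.Expr] | None = None,
    sources: tuple[str, ...] = ("lump", "qss", "conservation", "extra"),
    name: str = "reduced",
) -> ReducedModel:
    """Derive the reduced ODE system for a proper lumping scheme."""
    if fractions is None:
        fractions = solve_all(network, part, scheme, extra=extra, sources=sources)
    g = fractions.g()
    missing = [s for s in part.fast_species if s not in g]

    # substitution of original species by their back-translations
    subs_g = {sp.Symbol(s): e for s, e in g.items()}
    rs = [sp.cancel(r.subs(subs_g)) for r in part.rs]
    if missing:
        needed = {
            str(sym)
            for r in part.rs
            for sym in r.free_symbols
            if str(sym) in missing
        }
        if needed:
            raise ReductionError(
                f"slow rates reference species without back-translation: "
                f"{sorted(needed)}"
            )

    # parent-lump balance rates: ldot = M S_s r_s with g substituted
    Mpar = scheme.parent_matrix
    ldot_all = Mpar * sp.Matrix(part.Ss) * sp.Matrix(rs) if part.slow_reactions else sp.zeros(len(scheme.lumps), 1)
    ldot_all = sp.Matrix([sp.cancel(e) for e in ldot_all])

    Jfull = jacobian_correction(scheme, fractions, g=g)

    # constants: retained exact conservations
    x0 = dict(zip(network.species, network.initial_state()))
    constants = {
        lp.name: float(sum(x0[m] for m in lp.members)) for lp in scheme.constants()
    }
    const_syms = {sp.Symbol(k) for k in constants}

    # group dynamic lumps into blocks by fast cluster (lumps spanning
    # several clusters merge them)
    clusters = fast_clusters(part)
    import networkx as nx

    cg = nx.Graph()
    cg.add_nodes_from(range(len(clusters)))
    lump_clusters = {}
    for lp in scheme.lumps:
        cis = _cluster_of(lp, clusters)
        lump_clusters[lp.name] = cis
        for a_ci, b_ci in itertools.combinations(sorted(cis), 2):
            cg.add_edge(a_ci, b_ci)
    groups = [sorted(c) for c in nx.connected_components(cg)]
    groups.sort(key=lambda grp: grp[0])

    dynamic = scheme.dynamic()
    dyn_index = {lp.name: i for i, lp in enumerate(scheme.lumps)}
    blocks: list[ClusterBlock] = []
    rhs: dict[str, sp.Expr] = {}
    for grp in groups:
        names = [
            lp.name
            for lp in dynamic
            if lump_clusters[lp.name] and min(lump_clusters[lp.name]) in grp
        ]
        if not names:
            continue
        idx = [dyn_index[nm] for nm in names]
        Jb = Jfull[idx, idx]
        lb = sp.Matrix([ldot_all[i] for i in idx])
        symbolic = len(names) <= SYMBOLIC_INVERSE_MAX
        if symbolic:
            sol = _solve_linear_block(sp.eye(len(names)) + Jb, lb)
            for nm, e in zip(names, sol):
                rhs[nm] = e
        blocks.append(ClusterBlock(tuple(names), Jb, lb, symbolic))

    # pass-through slow species keep their own (substituted) ODEs
    S = stoichiometric_matrix(network).matrix
    slow_species = [s for s in network.species if s not in part.fast_species]
    slow_rates = {j: rs[k] for k, j in enumerate(part.slow_reactions)}
    for s in slow_species:
        i = network.index(s)
        expr = sp.Integer(0)
        for j in range(network.n_reactions):
            if S[i, j] == 0:
                continue
            if j not in slow_rates:
                raise ReductionError(
                    f"slow species {s!r} touched by fast reaction {j}"
                )
            expr += S[i, j] * slow_rates[j]
        rhs[s] = sp.cancel(expr)

    states = tuple(
        [lp.name for lp in dynamic if any(lp.name in b.lump_names for b in blocks)]
        + slow_species
    )
    model = ReducedModel(
        network=network,
        partition=part,
        scheme=scheme,
        fractions=fractions,
        states=states,
        rhs=rhs,
        constants=constants,
        blocks=tuple(blocks),
        g=g,
        name=name,
    )
    dets = model.det_correction(model.default_initial_state())
    for block_name, d in dets.items():
        if d <= 0:
            warnings.warn(
                f"det(I+J) = {d} <= 0 for block {block_name} at the initial "
                "condition",
                stacklevel=2,
            )
    return model


def naive_reduce(
    network: ReactionNetwork,
    part: FastSlowPartition,
    qss_species: list[str],
    conservation_eliminate: dict[str, str] | None = None,
    exact: "ConservationBasis | None" = None,
) -> ReducedModel:
    """Direct-substitution baseline: solve the fast balance equations for the
    declared QSS species and substitute into the remaining ODEs.

    ``conservation_eliminate`` maps additional species to exact conservation
    names used to eliminate them (the conservation is added to the solved
    system).  This approach is known to fail when the eliminated relations
    carry the slow coupling; it is provided for comparison.
    """
    conservation_eliminate = dict(conservation_eliminate or {})
    eliminate = list(qss_species) + list(conservation_eliminate)
    unknown_syms = [sp.Symbol(s) for s in eliminate]
    eqs = list(part.balance_equations())
    if exact is None:
        exact = exact_conservations(stoichiometric_matrix(network))
    for species, cons_name in conservation_eliminate.items():
        expr = exact.expressions()[cons_name] - sp.Symbol(cons_name)
        eqs.append(expr)
    sols = sp.solve(eqs, unknown_syms, dict=True)
    if not sols:
        raise ReductionError(
            "QSS equation system has no symbolic solution for "
            f"{eliminate} (direct substitution infeasible)"
        )
    sol = sols[0]
    missing = [s for s in unknown_syms if s not in sol]
    if missing:
        raise ReductionError(f"QSS system underdetermined for {missing}")
    subs = {s: sp.cancel(e) for s, e in sol.items()}

    S = stoichiometric_matrix(network).matrix
    rates = [sp.cancel(r.rate.subs(subs)) for r in network.reactions]
    states = tuple(s for s in network.species if s not in eliminate)
    rhs = {}
    for s in states:
        i = network.index(s)
        expr = sp.Add(
            *(S[i, j] * rates[j] for j in range(network.n_reactions) if S[i, j] != 0)
        )
        rhs[s] = sp.cancel(sp.expand(sp.together(expr)))

    x0 = dict(zip(network.species, network.initial_state()))
    constants = {
        nm: float(sum(c * x0[s] for c, s in zip(exact.row_by_name(nm), exact.species)))
        for nm in set(conservation_eliminate.values())
    }

    # degenerate scheme/fraction bookkeeping: identity over the states,
    # back-translation for eliminated species via the solution map
    from .lumping import Lump

    lumps = tuple(
        Lump(s, (s,), tuple(1 if t == s else 0 for t in states), s) for s in states
    )
    scheme = LumpingScheme(lumps, states)
    fps = FractionParameterSet(scheme)
    g = {s: sp.Symbol(s) for s in states}
    g.update({str(s): e for s, e in subs.items()})
    return ReducedModel(
        network=network,
        partition=part,
        scheme=scheme,
        fractions=fps,
        states=states,
        rhs=rhs,
        constants=constants,
        blocks=(),
        g=g,
        name="naive",
    )


def _equilibrate(
    network: ReactionNetwork,
    part: FastSlowPartition,
    params: dict[str, float],
    x0: np.ndarray,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fast-subsystem equilibrium consistent with the apparent conservations
    evaluated at x0 (solves balances + lump constraints, exact at QSS)."""
    apparent = apparent_conservations(part)
    psubs = {sp.Symbol(k): v for k, v in params.items()}
    syms = [sp.Symbol(s) for s in part.fast_species]
    balances = [e.subs(psubs) for e in part.balance_equations()]
    M = np.array(apparent.rows.tolist(), dtype=float)
    idx = [network.index(s) for s in part.fast_species]
    xf0 = x0[idx]
    targets = M @ xf0
    fns = [sp.lambdify((syms,), e, modules="numpy") for e in balances]

    def residual(z):
        bal = np.array([float(f(z)) for f in fns])
        lum = M @ z - targets
        return np.concatenate([bal, lum])

    res = least_squares(residual, xf0, xtol=3e-16, ftol=3e-16, gtol=None)
    if np.max(np.abs(residual(res.x))) > max(tol, 1e-6 * max(1.0, np.max(np.abs(targets)))):
        warnings.warn(
            f"fast-subsystem equilibration residual {np.max(np.abs(residual(res.x))):.2e}",
            stacklevel=2,
        )
    out = x0.copy()
    out[idx] = res.x
    return out


def reduced_initial_conditions(
    network: ReactionNetwork,
    reduced: ReducedModel,
    method: str = "equilibrate",
    params: dict[str, float] | None = None,
    horizon: float | None = None,
    t_burn: float | None = None,
    residual_tol: float = 1e-6,
) -> dict[str, float]:
    """Initial reduced state after the fast transient.

    ``equilibrate`` solves the fast balance/conservation system from the
    original initial condition; ``burn_in`` integrates the original model
    for a short window (default 1e-3 x horizon) and maps the end state;
    ``direct`` applies M_m to the raw initial condition.
    """
    p = network.merged_params(params)
    x0 = network.initial_state()
    part = reduced.partition
    if method == "direct":
        xeq = x0
    elif method == "equilibrate":
        xeq = _equilibrate(network, part, p, x0)
    elif method == "burn_in":
        if t_burn is None:
            if horizon is None:
                raise ReductionError("burn_in needs horizon or t_burn")
            t_burn = 1e-3 * horizon
        sol = solve_ivp(
            network.rhs_function(p),
            (0.0, t_burn),
            x0,
            method="LSODA",
            rtol=DEFAULT_RTOL,
            atol=DEFAULT_ATOL,
        )
        if not sol.success:
            raise ReductionError(f"burn-in integration failed: {sol.message}")
        xeq = sol.y[:, -1]
        # residual check: max relative fast-channel imbalance
        psubs = {sp.Symbol(k): v for k, v in p.items()}
        syms = [sp.Symbol(s) for s in part.fast_species]
        idx = [network.index(s) for s in part.fast_species]
        for e in part.balance_equations():
            terms = sp.Add.make_args(sp.expand(e.subs(psubs)))
            gross = sp.Add(*(sp.Abs(term) for term in terms))
            net = float(sp.lambdify((syms,), e.subs(psubs))(xeq[idx]))
            den = float(sp.lambdify((syms,), gross)(xeq[idx]))
            if den > 0 and abs(net) / den > residual_tol:
                warnings.warn(
                    f"burn-in did not settle: relative imbalance {abs(net) / den:.2e}",
                    stacklevel=2,
                )
    else:
        raise ReductionError(f"unknown initial-condition method {method!r}")
    state = dict(zip(network.species, xeq))
    lm0 = reduced.scheme.apply(state)
    return {s: (lm0[s] if s in lm0 else state[s]) for s in reduced.states}


def simulate(
    model: ReactionNetwork | ReducedModel,
    t_grid: np.ndarray,
    params: dict[str, float] | None = None,
    x0: dict[str, float] | np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate a network or reduced model onto a sampling grid (from t=0)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ReductionError("time grid must be strictly increasing")
    if isinstance(model, ReactionNetwork):
        names = model.species
        f = model.rhs_function(params)
        if x0 is None:
            y0 = model.initial_state()
        elif isinstance(x0, dict):
            y0 = np.array([x0[s] for s in names])
        else:
            y0 = np.asarray(x0, dtype=float)
        model_id = model.name
        p = model.merged_params(params)
    else:
        names = model.states
        f = model.rhs_function(params)
        if x0 is None:
            x0 = model.default_initial_state()
        if isinstance(x0, dict):
            y0 = np.array([x0[s] for s in names])
        else:
            y0 = np.asarray(x0, dtype=float)
        model_id = model.name
        p = model.parameter_values(params)
    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        f,
        (t0, float(t_grid[-1])),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_grid,
        dense_output=False,
    )
    if not sol.success:
        raise ReductionError(f"integration failed: {sol.message}")
    values = {nm: sol.y[i] for i, nm in enumerate(names)}
    return Trajectory(t=sol.t, values=values, model_id=model_id, params=p)


def eliminate_state(
    reduced: ReducedModel,
    conservation: str,
    solve_for: str,
    exact: "ConservationBasis | None" = None,
) -> ReducedModel:
    """Use an exact conservation of the original model, expressed through the
    back-translation map, as a first integral to eliminate one dynamic state.

    The invariant ``Z = sum_i m_i g_i(lm)`` is solved symbolically for
    ``solve_for``; among the roots, the one matching the (equilibrated)
    initial condition numerically is substituted into the remaining rhs.
    """
    if exact is None:
        exact = exact_conservations(stoichiometric_matrix(reduced.network))
    row = dict(zip(exact.species, exact.row_by_name(conservation)))
    Z = sp.Integer(0)
    for s, c in row.items():
        if c == 0:
            continue
        if s in reduced.g:
            Z += c * reduced.g[s]
        elif s in reduced.states:
            Z += c * sp.Symbol(s)
        else:
            raise ReductionError(f"cannot express {s!r} in reduced states")
    x0 = dict(zip(reduced.network.species, reduced.network.initial_state()))
    value = float(sum(c * x0[s] for s, c in row.items()))
    target = sp.Symbol(solve_for)
    roots = sp.solve(sp.together(Z - value), target)
    if not roots:
        raise ReductionError(f"invariant not solvable for {solve_for!r}")

    ic = reduced_initial_conditions(reduced.network, reduced, method="equilibrate")
    subs0 = {sp.Symbol(k): v for k, v in {**ic, **reduced.constants,
             **reduced.parameter_values()}.items()}
    best, best_err = None, np.inf
    for r in roots:
        try:
            err = abs(float(r.subs(subs0)) - ic[solve_for])
        except (TypeError, ValueError):
            continue
        if err < best_err:
            best, best_err = r, err
    if best is None:
        raise ReductionError("no real root matches the initial condition")

    repl = {target: best}
    states = tuple(s for s in reduced.states if s != solve_for)
    rhs = {s: sp.cancel(reduced.rhs[s].subs(repl)) for s in states}
    g = {s: sp.cancel(e.subs(repl)) for s, e in reduced.g.items()}
    g[solve_for] = best
    constants = dict(reduced.constants)
    constants[conservation] = value
    blocks = tuple(
        ClusterBlock(
            tuple(nm for nm in b.lump_names if nm != solve_for),
            b.J,
            b.ldot,
            True,
        )
        for b in reduced.blocks
    )
    return ReducedModel(
        network=reduced.network,
        partition=reduced.partition,
        scheme=reduced.scheme,
        fractions=reduced.fractions,
        states=states,
        rhs=rhs,
        constants=constants,
        blocks=blocks,
        g=g,
        name=reduced.name + f"-minus-{solve_for}",
    )


def count_parameters(reduced: ReducedModel) -> int:
    """Distinct parameters in the reduced dynamics, counting rate-constant
    pairs that occur only through their ratio (equilibrium constants) once.

    Ratio detection is numerical: a pair merges when jointly rescaling both
    constants leaves every right-hand side invariant at random positive
    states (a scale-invariance probe, robust to root expressions that defeat
    symbolic cancellation)."""
    param_names = set(reduced.network.parameters)
    exprs = [reduced.rhs[s] for s in reduced.states]
    present = sorted(
        {str(s) for e in exprs for s in e.free_symbols if str(s) in param_names}
    )
    if not present:
        return 0
    other_syms = sorted(
        {str(s) for e in exprs for s in e.free_symbols if str(s) not in param_names}
    )
    syms = [sp.Symbol(s) for s in present + other_syms]
    fns = [sp.lambdify(syms, e, modules="numpy") for e in exprs]
    rng = np.random.default_rng(20211140)
    points = rng.uniform(0.3, 2.0, size=(3, len(syms)))

    def values(scale_pair=None, factor=1.0):
        out = []
        for pt in points:
            args = pt.copy()
            if scale_pair is not None:
                for name in scale_pair:
                    args[present.index(name)] *= factor
            out.append([float(f(*args)) for f in fns])
        return np.array(out)

    base = values()
    remaining = list(present)
    ratios = 0
    i = 0
    while i < len(remaining):
        merged = False
        for kb in remaining[i + 1 :]:
            ka = remaining[i]
            ok = all(
                np.allclose(values((ka, kb), c), base, rtol=1e-8, atol=1e-12)
                for c in (1.7, 23.0)
            )
            if ok:
                remaining.remove(kb)
                remaining.remove(ka)
                ratios += 1
                merged = True
                break
        if not merged:
            i += 1
    return len(remaining) + ratios
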