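"""Back-translation of reduced trajectories and the relative-difference
measure eps_i(t) = |x_o(t) - x_r(t)| / x_o(t), with robustness scans over
parameter scalings."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sympy as sp

from .network import NetworkError, ReactionNetwork
from .reduction import (
    DEFAULT_ATOL,
    ReducedModel,
    Trajectory,
    reduced_initial_conditions,
    simulate,
)

__all__ = [
    "ComparisonSummary",
    "back_translate",
    "relative_difference",
    "compare_models",
    "robustness_scan",
    "format_scan",
]


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-species relative-difference series and their scalar summaries."""

    t: np.ndarray
    eps: dict[str, np.ndarray]  # per species, NaN where skipped
    skipped: dict[str, int]  # species -> number of skipped samples

    @property
    def max_mean(self) -> float:
        """Max over species of the time-mean of eps."""
        return max(float(np.nanmean(e)) for e in self.eps.values())

    @property
    def max_inf(self) -> float:
        """Max over species of the time-maximum of eps."""
        return max(float(np.nanmax(e)) for e in self.eps.values())

    def per_species(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": {s: float(np.nanmean(e)) for s, e in self.eps.items()},
                "inf": {s: float(np.nanmax(e)) for s, e in self.eps.items()},
                "skipped": self.skipped,
            }
        )


def back_translate(
    traj: Trajectory,
    reduced: ReducedModel,
    species: tuple[str, ...] | None = None,
    params: dict[str, float] | None = None,
) -> Trajectory:
    """Original-species trajectories from a reduced trajectory via the
    fraction parameters (no re-simulation)."""
    species = species or reduced.network.species
    subs = reduced._subs_numeric(params)
    syms = reduced.state_symbols()
    cols = [traj.values[s] for s in reduced.states]
    out: dict[str, np.ndarray] = {}
    missing: list[str] = []
    ones = np.ones_like(traj.t)
    for s in species:
        if s in traj.values:
            out[s] = traj.values[s]
            continue
        if s not in reduced.g:
            missing.append(s)
            continue
        fn = sp.lambdify(syms, reduced.g[s].subs(subs), modules="numpy")
        out[s] = np.asarray(fn(*cols), dtype=float) * ones
    if missing:
        raise NetworkError(f"non-back-translatable species: {missing}")
    return Trajectory(
        t=traj.t, values=out, model_id=traj.model_id + "+backtranslated",
        params=traj.params,
    )


def relative_difference(
    orig: Trajectory,
    red_bt: Trajectory,
    species: tuple[str, ...] | None = None,
    atol: float = DEFAULT_ATOL,
) -> ComparisonSummary:
    """eps per species on the common grid; samples where the original value
    is below ``atol`` in magnitude are skipped (NaN) and counted."""
    if orig.t.shape != red_bt.t.shape or not np.allclose(orig.t, red_bt.t):
        raise NetworkError("trajectories are on different time grids")
    species = species or tuple(s for s in orig.names if s in red_bt.values)
    eps: dict[str, np.ndarray] = {}
    skipped: dict[str, int] = {}
    for s in species:
        xo = orig.values[s]
        xr = red_bt.values[s]
        e = np.full_like(xo, np.nan)
        mask = np.abs(xo) > atol
        e[mask] = np.abs(xo[mask] - xr[mask]) / np.abs(xo[mask])
        eps[s] = e
        skipped[s] = int((~mask).sum())
    return ComparisonSummary(t=orig.t, eps=eps, skipped=skipped)


def compare_models(
    network: ReactionNetwork,
    reduced: ReducedModel,
    grid: np.ndarray,
    params: dict[str, float] | None = None,
    ic_method: str = "equilibrate",
) -> ComparisonSummary:
    """Simulate both models on a grid, back-translate, and measure eps.

    The reduced initial condition is rebuilt (equilibration or burn-in) at
    the given parameter point; the original model starts from its raw
    initial condition.
    """
    grid = np.asarray(grid, dtype=float)
    orig = simulate(network, grid, params=params)
    ic = reduced_initial_conditions(
        network, reduced, method=ic_method, params=params,
        horizon=float(grid[-1]),
    )
    red = simulate(reduced, grid, params=params, x0=ic)
    red_bt = back_translate(red, reduced, species=network.species, params=params)
    return relative_difference(orig, red_bt, species=network.species)


def robustness_scan(
    network: ReactionNetwork,
    reduced: ReducedModel,
    grid: np.ndarray,
    targets: list[str] | None = None,
    factors: tuple[float, ...] = (1e-2, 1e-1, 1e0, 1e1, 1e2),
    include_all: bool = True,
    ic_method: str = "equilibrate",
) -> pd.DataFrame:
    """One-at-a-time parameter scaling scan (plus a joint "All" row).

    Each cell re-simulates both models with the scaled parameters and
    rebuilt reduced initial conditions, and reports the (max-mean, max-inf)
    summary pair.  Failed cells are NaN and the scan continues.
    """
    if any(f <= 0 for f in factors):
        raise NetworkError("scale factors must be positive")
    targets = list(targets or network.parameters)
    rows = targets + (["All"] if include_all else [])
    data: dict[tuple[float, str], dict[str, float]] = {}
    for row in rows:
        for f in factors:
            if row == "All":
                overrides = {k: network.parameters[k] * f for k in targets}
            else:
                overrides = {row: network.parameters[row] * f}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    summary = compare_models(
                        network, reduced, grid, params=overrides,
                        ic_method=ic_method,
                    )
                cell = {"mean": summary.max_mean, "inf": summary.max_inf}
            except Exception as exc:  # noqa: BLE001 - scan must continue
                warnings.warn(f"scan cell ({row}, {f}) failed: {exc}", stacklevel=2)
                cell = {"mean": float("nan"), "inf": float("nan")}
            data.setdefault((f, "mean"), {})[row] = cell["mean"]
            data.setdefault((f, "inf"), {})[row] = cell["inf"]
    frame = pd.DataFrame(data)
    frame = frame[sorted(frame.columns, key=lambda c: (c[0], c[1] == "inf"))]
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["factor", "stat"])
    return frame.loc[rows]


def format_scan(frame: pd.DataFrame, digits: int = 2) -> pd.DataFrame:
    """Render a scan as 'mean/inf' cells, one column per factor."""
    factors = sorted({c[0] for c in frame.columns})

    def fmt(v: float) -> str:
        return "nan" if not np.isfinite(v) else f"{v:.{digits}g}"

    out = {}
    for f in factors:
        out[f"x{f:g}"] = [
            f"{fmt(frame.loc[row, (f, 'mean')])}/{fmt(frame.loc[row, (f, 'inf')])}"
            for row in frame.index
        ]
    return pd.DataFrame(out, index=frame.index)
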