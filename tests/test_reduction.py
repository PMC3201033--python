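"""Reduced-model derivation, initial conditions, simulation, consistency."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

from odezoom import (
    ReductionError,
    back_translate,
    build_scheme,
    count_parameters,
    derive_reduced,
    eliminate_state,
    naive_reduce,
    oracle_backtranslate,
    reduced_initial_conditions,
    simulate,
    small_example,
)
from odezoom.conservation import (
    apparent_conservations,
    exact_conservations,
    partition,
)
from odezoom.network import network_from_dict, stoichiometric_matrix

from conftest import rational_eq


class TestJacobianCorrection:
    def test_full_lump_scheme_has_zero_correction(self):
        """When every lump equals its apparent conservation row, J = 0 and
        the lump dynamics is the uncorrected balance M S_s r_s."""
        net = network_from_dict(
            {
                "species": {"A": 1.0, "B": 0.0, "D": 0.0},
                "parameters": {"kf": 1000.0, "kr": 1000.0, "s": 1.0},
                "reactions": ["A <-> B : kf*A - kr*B", "B -> D : s*B"],
            }
        )
        part = partition(net, [0])
        apparent = apparent_conservations(part)
        exact = exact_conservations(stoichiometric_matrix(net))
        scheme = build_scheme(apparent, exact, keep=[apparent.names[0]])
        red = derive_reduced(net, part, scheme)
        (block,) = red.blocks
        assert block.J.is_zero_matrix
        lump = scheme.lumps[0]
        s, B = sp.symbols("s B")
        # rhs = M_f S_s r_s with B substituted by its fraction of the lump
        g_B = red.g["B"]
        assert rational_eq(red.rhs[lump.name], -s * g_B)

    def test_small_example_scalar_correction(self, small, small_reduced):
        """dB/dt carries the factor (1 + K1 L1/(B+K1)^2)^-1 applied to
        (-B/(B+K1), 1) . (dL1/dt, dL2/dt)."""
        B, L1 = sp.symbols("B L1")
        k1, k_1, v_in, k_out = sp.symbols("k1 k_1 v_in k_out")
        K1 = k_1 / k1
        gC = small_reduced.g["C"]
        L1dot = v_in - k_out * gC
        L2dot = -k_out * gC
        corr = (1 + K1 * L1 / (B + K1) ** 2) ** -1
        assert rational_eq(
            small_reduced.rhs["B"], corr * (-B / (B + K1) * L1dot + L2dot)
        )
        assert rational_eq(small_reduced.rhs["L1"], L1dot)

    def test_glucose_five_state_block_structure(self, glucose, glucose_five):
        """Outer cluster: triangular correction (free external glucose is a
        full apparent row); inner cluster: the carrier-total row of J is
        zero, giving the printed (I+J) with a trailing unit row."""
        outer = next(b for b in glucose_five.blocks if "LE1" in b.lump_names)
        i = outer.lump_names.index("LE1")
        assert all(sp.cancel(outer.J[i, j]) == 0 for j in range(outer.J.shape[1]))
        inner = next(b for b in glucose_five.blocks if "LE2" in b.lump_names)
        i = inner.lump_names.index("LE2")
        assert all(sp.cancel(inner.J[i, j]) == 0 for j in range(inner.J.shape[1]))
        assert inner.J.shape == (3, 3)


class TestDeriveReduced:
    def test_enzyme_matches_printed_two_state_system(self, enzyme_reduced):
        """The derived rhs equals the printed pair of reduced ODEs with
        phi = D^3 + (M1+M3+M1 M3 (P+S)) D LE + M1 M3 LE^2, D = 1+M1 S+M3 P."""
        S, P, LE, k1, k_1, k2, k3, k_3 = sp.symbols("S P LE k1 k_1 k2 k3 k_3")
        M1, M3 = k1 / k_1, k3 / k_3
        D = 1 + M1 * S + M3 * P
        phi = D**3 + (M1 + M3 + M1 * M3 * (P + S)) * D * LE + M1 * M3 * LE**2
        assert rational_eq(
            enzyme_reduced.rhs["S"], -k2 * M1 * S * LE * (D**2 + M3 * LE) / phi
        )
        assert rational_eq(
            enzyme_reduced.rhs["P"], k2 * M1 * S * LE * (D**2 + M1 * LE) / phi
        )
        assert enzyme_reduced.states == ("S", "P")
        assert enzyme_reduced.constants == {"LE": 1.0}

    def test_enzyme_single_state_via_substrate_total(self, enzyme, enzyme_reduced):
        one = eliminate_state(enzyme_reduced, "LT", "P", exact=enzyme.exact)
        assert one.states == ("S",)
        assert count_parameters(one) == 3
        # trajectories agree with the two-state model
        grid = np.arange(0.1, 5.0001, 0.1)
        ic = reduced_initial_conditions(enzyme.network, enzyme_reduced)
        t2 = simulate(enzyme_reduced, grid, x0=ic)
        t1 = simulate(one, grid, x0={"S": ic["S"]})
        assert np.max(np.abs(t1.values["S"] - t2.values["S"])) < 1e-6

    def test_glucose_five_state_states(self, glucose_five):
        assert set(glucose_five.states) == {"LE1", "LE2", "Glce", "Glci", "G6Pi"}
        assert glucose_five.constants == {}

    def test_determinant_positive_along_trajectories(
        self, enzyme, enzyme_reduced, glucose, glucose_five
    ):
        for fx, red, t_end in [
            (enzyme, enzyme_reduced, 10.0),
            (glucose, glucose_five, 50.0),
        ]:
            ic = reduced_initial_conditions(fx.network, red)
            traj = simulate(red, np.linspace(t_end / 20, t_end, 20), x0=ic)
            for k in range(traj.t.size):
                state = {s: traj.values[s][k] for s in red.states}
                dets = red.det_correction(state)
                assert all(d > 0 for d in dets.values()), (fx.network.name, dets)

    def test_theorem_consistency_on_original_trajectory(self, enzyme, enzyme_reduced):
        """While QSS holds, d(lm)/dt measured by finite differences on the
        original trajectory matches the reduced rhs evaluated at M_m x(t)."""
        net = enzyme.network
        h = 1e-4
        times = [0.5, 1.0, 2.0]
        f = enzyme_reduced.rhs_function()
        sol = solve_ivp(
            net.rhs_function(), (0, 3.0), net.initial_state(),
            method="LSODA", rtol=1e-10, atol=1e-12, dense_output=True,
        )
        Mm = np.array(enzyme_reduced.scheme.matrix.tolist(), dtype=float)
        dyn = [enzyme_reduced.scheme.names.index(s) for s in enzyme_reduced.states]
        for t in times:
            lm_plus = (Mm @ sol.sol(t + h))[dyn]
            lm_minus = (Mm @ sol.sol(t - h))[dyn]
            fd = (lm_plus - lm_minus) / (2 * h)
            lm = (Mm @ sol.sol(t))[dyn]
            rhs = f(t, lm)
            assert np.allclose(fd, rhs, rtol=2e-3, atol=1e-8)


class TestNaiveReduction:
    def test_glucose_direct_substitution_decouples(self, glucose):
        nv = naive_reduce(
            glucose.network, glucose.partition, exact=glucose.exact,
            **glucose.naive_config,
        )
        assert set(nv.states) == {"E_Glce", "E_Glci", "Ee", "Ei"}
        al, be = sp.symbols("alpha beta")
        eg_e, eg_i, ee, ei = sp.symbols("E_Glce E_Glci Ee Ei")
        assert sp.expand(nv.rhs["E_Glce"] - al * (eg_i - eg_e)) == 0
        assert sp.expand(nv.rhs["Ee"] - be * (ei - ee)) == 0

    def test_zero_lock_failure_mode_from_raw_initial_conditions(self, glucose):
        """Started from the raw initial state the carrier-glucose complexes
        stay identically zero - the documented weakness of substitution."""
        nv = naive_reduce(
            glucose.network, glucose.partition, exact=glucose.exact,
            **glucose.naive_config,
        )
        traj = simulate(nv, np.linspace(1.0, 50.0, 25))
        assert np.max(np.abs(traj.values["E_Glce"])) == 0.0
        assert np.max(np.abs(traj.values["E_Glci"])) == 0.0

    def test_no_slow_reactions_gives_constant_states(self):
        net = network_from_dict(
            {
                "species": {"A": 1.0, "B": 1.0, "C": 0.0},
                "parameters": {"kf": 100.0, "kr": 50.0},
                "reactions": ["A + B <-> C : kf*A*B - kr*C"],
            }
        )
        part = partition(net, [0])
        nv = naive_reduce(net, part, qss_species=["C"])
        assert all(sp.simplify(e) == 0 for e in nv.rhs.values())

    def test_underdetermined_system_raises(self, glucose):
        with pytest.raises(ReductionError, match="underdetermined|no symbolic"):
            naive_reduce(
                glucose.network, glucose.partition,
                qss_species=["Glce", "Glci", "E_G6Pi", "E_Glc_G6Pi", "Ee"],
            )


class TestInitialConditions:
    def test_enzyme_equilibration_matches_analytic_value(self, enzyme, enzyme_reduced):
        ic = reduced_initial_conditions(enzyme.network, enzyme_reduced)
        assert ic["S"] == pytest.approx(np.sqrt(3) - 1, abs=1e-10)
        assert ic["P"] == pytest.approx(0.0, abs=1e-12)

    def test_burn_in_agrees_with_equilibration(self, enzyme, enzyme_reduced):
        eq = reduced_initial_conditions(enzyme.network, enzyme_reduced)
        with pytest.warns(UserWarning):
            bi = reduced_initial_conditions(
                enzyme.network, enzyme_reduced, method="burn_in", t_burn=0.02
            )
        # the burn-in also advances the slow variables a little
        assert bi["S"] == pytest.approx(eq["S"], abs=5e-3)

    def test_state_already_at_equilibrium_passes_through(self, small, small_reduced):
        net = small.network
        A, B, C = oracle_backtranslate(1.0, 1.0, net.parameters["k_1"] / net.parameters["k1"])
        eq_net = network_from_dict(
            {
                "species": {"A": A, "B": B, "C": C},
                "parameters": dict(net.parameters),
                "reactions": [
                    "A + B <-> C : k1*A*B - k_1*C",
                    "* -> A : v_in",
                    "C -> * : k_out*C",
                ],
                "closed": False,
            }
        )
        ic = reduced_initial_conditions(eq_net, small_reduced)
        assert ic["L1"] == pytest.approx(A + C, abs=1e-9)
        assert ic["B"] == pytest.approx(B, abs=1e-9)


class TestSimulation:
    def test_zero_rate_model_is_constant(self):
        net = network_from_dict({"species": {"A": 2.0}, "reactions": []})
        traj = simulate(net, np.linspace(0.1, 1.0, 5))
        assert np.allclose(traj.values["A"], 2.0)

    def test_reduced_enzyme_conserves_substrate_total(self, enzyme, enzyme_reduced):
        """S + P + (eta_CS + eta_CP) LE stays at LT along the reduced
        trajectory (the reduction preserves the exact conservation)."""
        ic = reduced_initial_conditions(enzyme.network, enzyme_reduced)
        grid = np.arange(0.1, 10.0001, 0.1)
        traj = simulate(enzyme_reduced, grid, x0=ic)
        bt = back_translate(traj, enzyme_reduced, species=enzyme.network.species)
        total = bt.values["S"] + bt.values["P"] + bt.values["CS"] + bt.values["CP"]
        assert np.max(np.abs(total - total[0])) < 1e-7

    def test_decreasing_grid_rejected(self, enzyme):
        with pytest.raises(ReductionError, match="strictly increasing"):
            simulate(enzyme.network, np.array([0.2, 0.1]))


class TestOracleEquivalence:
    def test_eta_route_matches_closed_form_route(self, small, small_reduced):
        """The two-state (L1, B) reduced model back-translated through the
        fraction parameters agrees with integrating the lump balances
        (L1, L2) and applying the closed-form quadratic solution."""
        net = small.network
        p = net.parameters
        K1 = p["k_1"] / p["k1"]
        grid = np.arange(0.05, 20.0001, 0.05)
        B0 = oracle_backtranslate(1.0, 1.0, K1)[1]
        t1 = simulate(
            small_reduced, grid, x0={"L1": 1.0, "B": B0}, rtol=1e-10, atol=1e-12
        )
        bt = back_translate(t1, small_reduced, species=net.species)

        def lump_rhs(t, y):
            _, _, C = oracle_backtranslate(y[0], y[1], K1)
            return [p["v_in"] - p["k_out"] * C, -p["k_out"] * C]

        sol = solve_ivp(
            lump_rhs, (0, grid[-1]), [1.0, 1.0], method="LSODA",
            rtol=1e-10, atol=1e-12, t_eval=grid,
        )
        oracle = np.array(
            [oracle_backtranslate(l1, l2, K1) for l1, l2 in sol.y.T]
        )
        for i, s in enumerate(("A", "B", "C")):
            rel = np.max(
                np.abs(bt.values[s] - oracle[:, i])
                / np.maximum(np.abs(oracle[:, i]), 1e-12)
            )
            assert rel < 1e-6, s

    def test_error_shrinks_with_timescale_separation(self):
        """Scaling the fast rates by lambda in {1e2, 1e3, 1e4} (slow flows
        fixed) makes the worst-case relative difference decrease."""
        from odezoom.validation import compare_models

        errs = []
        for lam in (1e2, 1e3, 1e4):
            fx = small_example(k1=lam, k_minus1=2 * lam)
            red = derive_reduced(fx.network, fx.partition, fx.schemes["two_state"])
            summary = compare_models(
                fx.network, red, np.arange(0.1, 20.0001, 0.1)
            )
            errs.append(summary.max_inf)
        assert errs[0] > errs[1] > errs[2]
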