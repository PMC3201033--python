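"""Fraction parameters: relation collection, symbolic solving, invariants."""

import math

import numpy as np
import pytest
import sympy as sp

from odezoom import (
    NonBackTranslatableError,
    collect_relations,
    fractions_with_constraint,
    solve_all,
    solve_fractions,
)
from odezoom.network import network_from_dict
from odezoom.conservation import partition as make_partition
from odezoom.lumping import build_scheme
from odezoom.conservation import apparent_conservations, exact_conservations
from odezoom.network import stoichiometric_matrix

from conftest import rational_eq


def sum_to_one(lf) -> bool:
    total = sp.together(sp.Add(*lf.eta.values()) - 1)
    return sp.expand(sp.fraction(total)[0]) == 0


class TestCollectRelations:
    def test_enzyme_lump_gets_definition_and_balances(self, enzyme):
        relset = collect_relations(
            enzyme.network, enzyme.partition, enzyme.schemes["two_state"], "LE"
        )
        provs = [r.provenance for r in relset.relations]
        assert provs.count("lump") == 1
        assert provs.count("qss") == 2  # both fast channels touch E
        assert relset.n_m == 3

    def test_glucose_outer_lump_two_relations(self, glucose):
        relset = collect_relations(
            glucose.network, glucose.partition, glucose.schemes["five_state"], "LE1"
        )
        provs = [r.provenance for r in relset.relations]
        # definition + the single outer binding balance (+ usable
        # conservation rows); the first nonsingular pair is (def, balance)
        assert provs[0] == "lump"
        assert "qss" in provs

    def test_nonlinear_relation_rejected(self):
        """A constraint quadratic in two lump members fails the joint
        linearity check and is dropped."""
        net = network_from_dict(
            {
                "species": {"A": 1.0, "B": 1.0, "C": 0.0, "D": 0.0},
                "parameters": {"kf": 100.0, "kr": 100.0, "s": 1.0},
                "reactions": ["A + B <-> C : kf*A*B - kr*C", "C -> D : s*C"],
            }
        )
        part = make_partition(net, [0])
        apparent = apparent_conservations(part)
        exact = exact_conservations(stoichiometric_matrix(net))
        keep = apparent.names[0]
        scheme = build_scheme(apparent, exact, keep=[keep])
        lump = next(l for l in scheme.lumps if l.width > 1)
        m1, m2 = (sp.Symbol(m) for m in lump.members[:2])
        relset = collect_relations(
            net, part, scheme, lump.name, extra=[m1 * m2 - 1]
        )
        assert all(r.provenance != "extra" for r in relset.relations)


class TestSolveFractions:
    def test_enzyme_fractions_match_closed_forms(self, enzyme):
        """eta_E = 1/(1 + M1 S + M3 P) etc., with M1 = k1/k-1, M3 = k3/k-3."""
        fps = solve_all(enzyme.network, enzyme.partition, enzyme.schemes["two_state"])
        S, P, k1, k_1, k3, k_3 = sp.symbols("S P k1 k_1 k3 k_3")
        D = 1 + (k1 / k_1) * S + (k3 / k_3) * P
        lf = fps.solved["LE"]
        assert rational_eq(lf.eta["E"], 1 / D)
        assert rational_eq(lf.eta["CS"], (k1 / k_1) * S / D)
        assert rational_eq(lf.eta["CP"], (k3 / k_3) * P / D)

    def test_small_example_fractions(self, small):
        fps = solve_all(small.network, small.partition, small.schemes["two_state"])
        B, k1, k_1 = sp.symbols("B k1 k_1")
        K1 = k_1 / k1
        lf = fps.solved["L1"]
        assert rational_eq(lf.eta["A"], K1 / (B + K1))
        assert rational_eq(lf.eta["C"], B / (B + K1))

    def test_glucose_five_state_fractions(self, glucose):
        fps = solve_all(
            glucose.network, glucose.partition, glucose.schemes["five_state"]
        )
        Glce, Glci, G6Pi = sp.symbols("Glce Glci G6Pi")
        k1, k_1, k2, k_2, k3, k_3, k4, k_4 = sp.symbols(
            "k1 k_1 k2 k_2 k3 k_3 k4 k_4"
        )
        K1, K2, K3, K4 = k_1 / k1, k_2 / k2, k_3 / k3, k_4 / k4
        outer = fps.solved["LE1"]
        assert rational_eq(outer.eta["Ee"], K1 / (K1 + Glce))
        assert rational_eq(outer.eta["E_Glce"], Glce / (K1 + Glce))
        inner = fps.solved["LE2"]
        xi = G6Pi * (K4 * Glci + K2 * K3) + K3 * K4 * Glci + K2 * K3 * K4
        assert rational_eq(inner.eta["Ei"], K2 * K3 * K4 / xi)
        assert rational_eq(inner.eta["E_Glci"], K3 * K4 * Glci / xi)
        assert rational_eq(inner.eta["E_G6Pi"], K2 * K3 * G6Pi / xi)
        assert rational_eq(inner.eta["E_Glc_G6Pi"], K4 * G6Pi * Glci / xi)

    def test_glucose_four_state_g6p_fractions(self, glucose):
        """The G6P lump solution with xi = K3 K4 + K4 x_EGlci + K3 x_Ei,
        the carrier amounts entering as frozen foreign coefficients."""
        fps = solve_all(
            glucose.network, glucose.partition, glucose.schemes["four_state"]
        )
        EGlci, Ei = sp.symbols("E_Glci Ei")
        k3, k_3, k4, k_4 = sp.symbols("k3 k_3 k4 k_4")
        K3, K4 = k_3 / k3, k_4 / k4
        xi = K3 * K4 + K4 * EGlci + K3 * Ei
        lf = fps.solved["LG6P"]
        assert rational_eq(lf.eta["E_G6Pi"], K3 * Ei / xi)
        assert rational_eq(lf.eta["E_Glc_G6Pi"], K4 * EGlci / xi)
        assert rational_eq(lf.eta["G6Pi"], K3 * K4 / xi)

    def test_singleton_lump_unit_fraction(self, enzyme):
        fps = solve_all(enzyme.network, enzyme.partition, enzyme.schemes["two_state"])
        assert fps.solved["S"].eta == {"S": sp.Integer(1)}

    def test_sum_eta_equals_one_everywhere(self, enzyme, glucose, small):
        for fx, scheme in [
            (enzyme, "two_state"),
            (glucose, "four_state"),
            (glucose, "five_state"),
            (small, "two_state"),
        ]:
            fps = solve_all(fx.network, fx.partition, fx.schemes[scheme])
            for lf in fps.solved.values():
                assert sum_to_one(lf), lf.lump.name

    def test_numeric_spot_value(self, enzyme):
        """eta_E at M1 = 0.5, S = sqrt(3)-1, P = 0 evaluates to about
        0.7320508 (the same number as the equilibrated substrate)."""
        fps = solve_all(enzyme.network, enzyme.partition, enzyme.schemes["two_state"])
        val = fps.solved["LE"].eta["E"].subs(
            {
                sp.Symbol("S"): math.sqrt(3) - 1,
                sp.Symbol("P"): 0,
                sp.Symbol("k1"): 1000,
                sp.Symbol("k_1"): 2000,
                sp.Symbol("k3"): 3000,
                sp.Symbol("k_3"): 1000,
            }
        )
        assert abs(float(val) - 0.7320508) < 1e-6

    def test_monomolecular_network_constant_fractions(self):
        """In a first-order (linear) network the fractions depend on the
        rate constants only, recovering the linear-model limit."""
        net = network_from_dict(
            {
                "species": {"X": 1.0, "Y": 0.0, "Z": 0.0},
                "parameters": {"kf": 500.0, "kr": 250.0, "s": 1.0},
                "reactions": ["X <-> Y : kf*X - kr*Y", "Y -> Z : s*Y"],
            }
        )
        part = make_partition(net, [0])
        apparent = apparent_conservations(part)
        exact = exact_conservations(stoichiometric_matrix(net))
        lump_name = apparent.names[0]
        scheme = build_scheme(apparent, exact, keep=[lump_name])
        fps = solve_all(net, part, scheme)
        state_syms = {sp.Symbol(s) for s in net.species}
        for lf in fps.solved.values():
            for e in lf.eta.values():
                assert not (e.free_symbols & state_syms)

    def test_back_substitution_residuals_vanish(self, glucose):
        fps = solve_all(
            glucose.network, glucose.partition, glucose.schemes["five_state"]
        )
        for lf in fps.solved.values():
            if not lf.relations_used:
                continue
            L = sp.Symbol(lf.lump.name)
            subs = {sp.Symbol(m): sp.together(e * L) for m, e in lf.eta.items()}
            for rel in lf.relations_used:
                res = sp.together(rel.expr.subs(subs))
                assert sp.expand(sp.fraction(res)[0]) == 0


class TestConstrainedFractions:
    def test_six_member_solution_structure(self, glucose):
        """The full-carrier lump solved with the constant-regional-
        transporter constraint: the solution satisfies the defining system
        and the pairwise ratios implied by the binding equilibria."""
        fps = fractions_with_constraint(
            glucose.network,
            glucose.partition,
            glucose.schemes["three_state_constrained"],
            glucose.extra_constraints["three_state_constrained"],
        )
        lf = fps.solved["LE"]
        assert [r.provenance for r in lf.relations_used] == [
            "lump", "qss", "qss", "qss", "qss", "extra"
        ]
        assert sum_to_one(lf)
        Glce, Glci, G6Pi = sp.symbols("Glce Glci G6Pi")
        k1, k_1, k2, k_2, k3, k_3, k4, k_4, al, be = sp.symbols(
            "k1 k_1 k2 k_2 k3 k_3 k4 k_4 alpha beta"
        )
        assert rational_eq(lf.eta["E_G6Pi"] / lf.eta["Ei"], k4 / k_4 * G6Pi)
        assert rational_eq(lf.eta["E_Glce"] / lf.eta["Ee"], k1 / k_1 * Glce)
        assert rational_eq(lf.eta["E_Glci"] / lf.eta["Ei"], k2 / k_2 * Glci)
        assert rational_eq(
            lf.eta["E_Glc_G6Pi"] / lf.eta["E_Glci"], k3 / k_3 * G6Pi
        )
        # free-carrier split carries the constraint's alpha/beta structure
        assert rational_eq(
            lf.eta["Ee"] / lf.eta["Ei"],
            (be + al * k2 / k_2 * Glci) / (be + al * k1 / k_1 * Glce),
        )

    def test_symmetric_constraint_gives_symmetric_fractions(self, glucose):
        """With alpha = beta, equal binding constants and a symmetric state
        the inner/outer carrier fractions coincide."""
        fps = fractions_with_constraint(
            glucose.network,
            glucose.partition,
            glucose.schemes["three_state_constrained"],
            glucose.extra_constraints["three_state_constrained"],
        )
        lf = fps.solved["LE"]
        subs = {
            sp.Symbol("alpha"): 1, sp.Symbol("beta"): 1,
            sp.Symbol("k1"): 2, sp.Symbol("k_1"): 1,
            sp.Symbol("k2"): 2, sp.Symbol("k_2"): 1,
            sp.Symbol("k3"): 1, sp.Symbol("k_3"): 1,
            sp.Symbol("k4"): 1, sp.Symbol("k_4"): 1,
            sp.Symbol("Glce"): sp.Rational(1, 3),
            sp.Symbol("Glci"): sp.Rational(1, 3),
        }
        assert sp.simplify(
            (lf.eta["Ee"] - lf.eta["Ei"]).subs(subs)
        ) == 0
        assert sp.simplify(
            (lf.eta["E_Glce"] - lf.eta["E_Glci"]).subs(subs)
        ) == 0

    def test_degenerate_constraint_detected(self, glucose):
        """A constraint linearly dependent on the binding balances leaves
        the system rank deficient; the lump is reported non-back-
        translatable instead of being regularised."""
        scheme = glucose.schemes["three_state_constrained"]
        k1, k_1 = sp.symbols("k1 k_1")
        Ee, Glce, EGlce = sp.symbols("Ee Glce E_Glce")
        duplicate = k1 * Ee * Glce - k_1 * EGlce  # balance 1 again
        with pytest.raises(NonBackTranslatableError):
            fractions_with_constraint(
                glucose.network, glucose.partition, scheme, [duplicate]
            )


class TestComposition:
    def test_composed_g_uses_only_states_and_parameters(self, glucose):
        fps = solve_all(
            glucose.network, glucose.partition, glucose.schemes["four_state"]
        )
        g = fps.g()
        states = {sp.Symbol(l.name) for l in glucose.schemes["four_state"].lumps}
        params = {sp.Symbol(p) for p in glucose.network.parameters}
        for s, e in g.items():
            assert e.free_symbols <= states | params, s
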