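import numpy as np
import pytest
import sympy as sp

from odezoom import (
    derive_reduced,
    enzyme_kinetics,
    glucose_transport,
    small_example,
)


def rational_eq(a, b) -> bool:
    """Equality of rational(-function) expressions by cross-multiplied
    polynomial expansion (no GCD heuristics involved)."""
    num, _den = sp.fraction(sp.cancel(sp.together(a - b)))
    return sp.expand(num) == 0


@pytest.fixture(scope="session")
def enzyme():
    return enzyme_kinetics()


@pytest.fixture(scope="session")
def enzyme_reduced(enzyme):
    return derive_reduced(
        enzyme.network, enzyme.partition, enzyme.schemes["two_state"]
    )


@pytest.fixture(scope="session")
def glucose():
    return glucose_transport()


@pytest.fixture(scope="session")
def glucose_five(glucose):
    return derive_reduced(
        glucose.network, glucose.partition, glucose.schemes["five_state"]
    )


@pytest.fixture(scope="session")
def small():
    return small_example()


@pytest.fixture(scope="session")
def small_reduced(small):
    return derive_reduced(small.network, small.partition, small.schemes["two_state"])


@pytest.fixture()
def enzyme_doc():
    """A raw native-format mapping for the enzyme model (for parser tests)."""
    return {
        "name": "enzyme",
        "species": {"S": 1.0, "E": 1.0, "P": 0.0, "CS": 0.0, "CP": 0.0},
        "parameters": {"k1": 1000, "k_1": 2000, "k2": 1, "k3": 3000, "k_3": 1000},
        "reactions": [
            "S + E <-> CS : k1*S*E - k_1*CS",
            "CS -> CP : k2",
            "CP <-> P + E : k_3*CP - k3*P*E",
        ],
    }


@pytest.fixture()
def grid_enzyme():
    return np.arange(0.1, 10.0001, 0.1)
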