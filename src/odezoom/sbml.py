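"""A restricted SBML Level 2/3 core importer.

Supports the ODE subset this tool operates on: species with initial
amounts/concentrations, global and reaction-local parameters, and
reactions with MathML kinetic laws.  Constructs outside that subset
(events, rules, function definitions, constraints) raise
:class:`UnsupportedSBMLError` naming the construct.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import sympy as sp

from .network import NetworkError, Reaction, ReactionNetwork, TIME

__all__ = ["read_sbml", "read_sbml_string", "UnsupportedSBMLError"]


class UnsupportedSBMLError(NetworkError):
    """An SBML construct outside the supported ODE subset."""


_MATHML_NS = "{http://www.w3.org/1998/Math/MathML}"

_UNSUPPORTED = {
    "listOfEvents": "event",
    "listOfRules": "rule",
    "listOfConstraints": "constraint",
    "listOfFunctionDefinitions": "functionDefinition",
}


def _local(tag: str) -> str:
    return tag.split("}", 1)[-1]


def _math_to_sympy(node: ET.Element, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    tag = _local(node.tag)
    if tag == "math":
        kids = list(node)
        if len(kids) != 1:
            raise UnsupportedSBMLError("kinetic law <math> must have one child")
        return _math_to_sympy(kids[0], symbols)
    if tag == "ci":
        name = (node.text or "").strip()
        if name == "t":
            return TIME
        if name not in symbols:
            raise NetworkError(f"kinetic law references undeclared symbol {name!r}")
        return symbols[name]
    if tag == "cn":
        sbml_type = node.attrib.get("type", "real")
        text = (node.text or "").strip()
        if sbml_type in ("integer", "real"):
            return sp.Rational(text) if sbml_type == "integer" else sp.Float(text)
        if sbml_type == "rational":
            sep = node.find(_MATHML_NS + "sep")
            num = int(text)
            den = int((sep.tail or "").strip()) if sep is not None else 1
            return sp.Rational(num, den)
        raise UnsupportedSBMLError(f"<cn> type {sbml_type!r}")
    if tag == "apply":
        kids = list(node)
        op, args = _local(kids[0].tag), kids[1:]
        terms = [_math_to_sympy(a, symbols) for a in args]
        if op == "plus":
            return sp.Add(*terms) if terms else sp.Integer(0)
        if op == "times":
            return sp.Mul(*terms) if terms else sp.Integer(1)
        if op == "minus":
            if len(terms) == 1:
                return -terms[0]
            if len(terms) == 2:
                return terms[0] - terms[1]
            raise UnsupportedSBMLError("n-ary <minus>")
        if op == "divide":
            if len(terms) != 2:
                raise UnsupportedSBMLError("non-binary <divide>")
            return terms[0] / terms[1]
        if op == "power":
            if len(terms) != 2:
                raise UnsupportedSBMLError("non-binary <power>")
            return terms[0] ** terms[1]
        raise UnsupportedSBMLError(f"MathML operator <{op}>")
    raise UnsupportedSBMLError(f"MathML element <{tag}>")


def read_sbml_string(text: str) -> ReactionNetwork:
    root = ET.fromstring(text)
    model = next((el for el in root.iter() if _local(el.tag) == "model"), None)
    if model is None:
        raise NetworkError("no <model> element found")

    for child in model:
        tag = _local(child.tag)
        if tag in _UNSUPPORTED and len(child):
            raise UnsupportedSBMLError(f"unsupported feature: {_UNSUPPORTED[tag]}")

    species: list[tuple[str, float]] = []
    for el in model.iter():
        if _local(el.tag) != "species":
            continue
        sid = el.attrib["id"]
        amount = el.attrib.get("initialAmount", el.attrib.get("initialConcentration", "0"))
        species.append((sid, float(amount)))

    parameters: dict[str, float] = {}
    for el in model.iter():
        if _local(el.tag) in ("parameter", "localParameter") and "id" in el.attrib:
            parameters[el.attrib["id"]] = float(el.attrib.get("value", "nan"))

    symbols = {s: sp.Symbol(s) for s, _ in species}
    symbols.update({p: sp.Symbol(p) for p in parameters})

    reactions: list[Reaction] = []
    for el in model.iter():
        if _local(el.tag) != "reaction":
            continue
        rid = el.attrib.get("id", f"r{len(reactions) + 1}")
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        math = None
        for container in el:
            tag = _local(container.tag)
            if tag in ("listOfReactants", "listOfProducts"):
                dest = reactants if tag == "listOfReactants" else products
                for ref in container:
                    if _local(ref.tag) != "speciesReference":
                        continue
                    stoich = int(float(ref.attrib.get("stoichiometry", "1")))
                    dest[ref.attrib["species"]] = dest.get(ref.attrib["species"], 0) + stoich
            elif tag == "kineticLaw":
                for sub in container:
                    if _local(sub.tag) == "math":
                        math = sub
        if math is None:
            raise UnsupportedSBMLError(f"reaction {rid!r} has no kinetic law")
        reversible = el.attrib.get("reversible", "false").lower() == "true"
        rate = _math_to_sympy(math, symbols)
        reactions.append(Reaction(rid, reactants, products, rate, reversible))

    return ReactionNetwork(
        species,
        parameters,
        reactions,
        closed=True,
        name=model.attrib.get("id", "sbml_model"),
    )


def read_sbml(path: str) -> ReactionNetwork:
    with open(path) as fh:
        return read_sbml_string(fh.read())
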