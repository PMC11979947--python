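"""SBML Level 3 export / import of a built network.

The writer emits standards-shaped SBML L3v2 (compartment, species with
``boundaryCondition`` for the clamped pools, reactions with explicit
content-MathML kinetic laws generated symbolically) without depending on
libsbml.  A structured annotation on the model element carries the exact
network serialization, which the importer uses for a lossless round trip.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import sympy as sp

from ..model_assembly import ReactionNetwork
from ..rate_laws import CONSTANT_FLUX_GUARD, MECHANISMS

__all__ = ["export_sbml", "import_sbml", "validate_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOTATION_NS = "https://tcaflux.invalid/network-serialization"


# ---------------------------------------------------------------------------
# symbolic rate expressions (for the MathML kinetic laws)
# ---------------------------------------------------------------------------

def _symbolic_rate(rxn) -> sp.Expr:
    p = rxn.params
    roles = MECHANISMS[p.mechanism].roles
    # underscores trigger prefixed subscript markup in sympy's MathML
    # printer, so species ids are flattened inside the kinetic-law math
    c = {role: sp.Symbol(rxn.bindings[role].replace("_", ""))
         for role in roles}
    km = {k: sp.Float(v) for k, v in p.km.items()}
    vf = sp.Float(p.vmaxf) if p.vmaxf is not None else None
    vr = sp.Float(p.vmaxr) if p.vmaxr is not None else None
    keq = sp.Float(p.keq) if p.keq is not None else None
    m = p.mechanism
    if m == "ter_bi":
        A, B, C, P, Q = (c[r] for r in "ABCPQ")
        Ka, Kb, Kc, Kp, Kq = (km[k] for k in ("Ka", "Kb", "Kc", "Kp", "Kq"))
        expr = (vf / (Ka * Kb * Kc)) * (A * B * C - P * Q / keq) / (
            1 + A / Ka + A * B / (Ka * Kb) + A * B * C / (Ka * Kb * Kc)
            + P * Q / (Kp * Kq) + Q / Kq)
    elif m == "random_bi_bi":
        A, B, P, Q = (c[r] for r in "ABPQ")
        Ka, Kb, Kp, Kq = (km[k] for k in ("Ka", "Kb", "Kp", "Kq"))
        expr = (vf / (Ka * Kb)) * (A * B - P * Q / keq) / (
            1 + A / Ka + B / Kb + A * B / (Ka * Kb) + P / Kp + Q / Kq
            + P * Q / (Kp * Kq) + A * Q / (Ka * Kq) + P * B / (Kp * Kb))
    elif m == "uni_uni":
        A, P = c["A"], c["P"]
        Ka, Kp = km["Ka"], km["Kp"]
        expr = (vf / Ka) * (A - P / keq) / (1 + A / Ka + P / Kp)
    elif m == "mwc_idh":
        A, B, P, Q = (c[r] for r in "ABPQ")
        Ka, Kb, Kp, Kq = (km[k] for k in ("Ka", "Kb", "Kp", "Kq"))
        n, L = sp.Float(p.n), sp.Float(p.L)
        ki_iso = sp.Float(p.ki["Ki_NADH_vs_Iso"])
        a = A / Ka
        if "Ki_NADH_vs_NAD" in p.ki:
            a = a / (1 + Q / sp.Float(p.ki["Ki_NADH_vs_NAD"]))
        beta = B / Kb
        expr = vf * ((a / (1 + a))
                     * beta * (1 + beta) ** (n - 1)
                     / (L * (1 + Q / ki_iso) ** n + (1 + beta) ** n)
                     - (P * Q / (Kp * Kq * keq))
                     / (1 + P / Kp + Q / Kq + P * Q / (Kp * Kq)))
    elif m == "bi_bi_inhib":
        A, B, P, Q = (c[r] for r in "ABPQ")
        GSH, NAD = c["GSH"], c["NAD"]
        Ka, Kb, Kp, Kq = (km[k] for k in ("Ka", "Kb", "Kp", "Kq"))
        expr = (vf / (Ka * Kb)) * (A * B - P * Q / keq) / (
            1 + A / Ka + A * GSH / (Ka * sp.Float(p.ki["Ki_GSH"]))
            + A * B / (Ka * Kb) + Q * B / (Kq * Kb) + Q * P / (Kq * Kp)
            + Q / Kq + NAD / sp.Float(p.ki["Ki_NAD"]))
    elif m == "ter_ter":
        A, B, C, P, Q, R = (c[r] for r in "ABCPQR")
        Ka, Kb, Kc, Kp, Kq, Kr = (km[k] for k in
                                  ("Ka", "Kb", "Kc", "Kp", "Kq", "Kr"))
        expr = (vf / (Ka * Kb * Kc)) * (A * B * C - P * Q * R / keq) / (
            1 + A / Ka + A * B / (Ka * Kb) + A * B * C / (Ka * Kb * Kc)
            + P * Q * R / (Kp * Kq * Kr) + Q * R / (Kq * Kr) + R / Kr)
    elif m == "bi_bi":
        A, B, P, Q = (c[r] for r in "ABPQ")
        Ka, Kb, Kp, Kq = (km[k] for k in ("Ka", "Kb", "Kp", "Kq"))
        expr = (vf / (Ka * Kb)) * (A * B - P * Q / keq) / (
            1 + A / Ka + A * B / (Ka * Kb) + P * Q / (Kp * Kq) + Q / Kq)
    elif m == "uni_uni_2V":
        A, P = c["A"], c["P"]
        Ka, Kp = km["Ka"], km["Kp"]
        expr = (vf * A / Ka - vr * P / Kp) / (1 + A / Ka + P / Kp)
    elif m == "bi_bi_2V":
        A, B, P, Q = (c[r] for r in "ABPQ")
        Ka, Kb, Kp, Kq = (km[k] for k in ("Ka", "Kb", "Kp", "Kq"))
        expr = (vf * A * B / (Ka * Kb) - vr * P * Q / (Kp * Kq)) / (
            1 + A / Ka + A * B / (Ka * Kb) + P * Q / (Kp * Kq) + Q / Kq)
    elif m == "gdh_mwc":
        A, B, P, Q, R = (c[r] for r in "ABPQR")
        GTP, ADP = c["GTP"], c["ADP"]
        Ka, Kb, Kp, Kq, Kr = (km[k] for k in ("Ka", "Kb", "Kp", "Kq", "Kr"))
        n, L = sp.Float(p.n), sp.Float(p.L)
        rho = R / Kr
        L_eff = (L * (1 + GTP / sp.Float(p.ki["Ki_GTP"])) ** n
                 / (1 + ADP / sp.Float(p.ka_act["Ka_ADP"])))
        expr = (vf * (A * B / (Ka * Kb)) / (1 + A / Ka + A * B / (Ka * Kb))
                - vr * (P * Q / (Kp * Kq)) / (1 + P / Kp + P * Q / (Kp * Kq))
                * rho * (1 + rho) ** (n - 1) / (L_eff + (1 + rho) ** n))
    elif m == "gr_bi_ter":
        A, B, P, Q = (c[r] for r in "ABPQ")
        R = Q
        Ka, Kb, Kp, Kq, Kr = (km[k] for k in ("Ka", "Kb", "Kp", "Kq", "Kr"))
        expr = (vf / (Ka * Kb)) * (A * B - P * Q * R / keq) / (
            1 + A / Ka + A * B / (Ka * Kb) + P * Q * R / (Kp * Kq * Kr)
            + Q * R / (Kq * Kr) + Q / Kq + R / Kr)
    elif m == "constant_flux":
        S = c["S"]
        expr = vf * S / (S + sp.Float(CONSTANT_FLUX_GUARD))
    else:  # pragma: no cover
        raise ValueError(f"no symbolic form for mechanism {m!r}")
    return sp.Float(rxn.activity) * expr


def _mathml(expr: sp.Expr) -> ET.Element:
    xml = sp.printing.mathml(expr)
    # sympy emits mml:-prefixed subscript markup for names with trailing
    # digits; bind that prefix to the MathML namespace as well
    wrapped = (f'<math xmlns="{MATHML_NS}" xmlns:mml="{MATHML_NS}">'
               f'{xml}</math>')
    return ET.fromstring(wrapped)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_sbml(net: ReactionNetwork, path: Path | None = None) -> str:
    """Serialize ``net`` as an SBML L3 document string (optionally saved)."""
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml",
                      {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model",
                          {"id": f"krebs_cycle_{net.tissue}",
                           "name": f"Krebs cycle model ({net.tissue})"})
    annot = ET.SubElement(model, f"{{{SBML_NS}}}annotation")
    payload = ET.SubElement(annot, f"{{{ANNOTATION_NS}}}network")
    payload.text = json.dumps(net.to_dict())

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "matrix", "size": "1", "constant": "true",
                   "spatialDimensions": "3"})
    specs = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in net.species.values():
        ET.SubElement(specs, f"{{{SBML_NS}}}species", {
            "id": s.id, "compartment": "matrix",
            "initialConcentration": repr(s.conc),
            "boundaryCondition": "true" if s.role == "fixed" else "false",
            "constant": "false",
            "hasOnlySubstanceUnits": "false"})

    rxns = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in net.reactions:
        rx = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction",
                           {"id": r.id, "name": r.name,
                            "reversible": "true"})
        reactants = {sp_: -co for sp_, co in r.stoichiometry.items() if co < 0}
        products = {sp_: co for sp_, co in r.stoichiometry.items() if co > 0}
        if reactants:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sp_, co in reactants.items():
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp_, "stoichiometry": repr(co),
                               "constant": "true"})
        if products:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sp_, co in products.items():
                ET.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp_, "stoichiometry": repr(co),
                               "constant": "true"})
        modifiers = [v for k, v in r.bindings.items()
                     if v not in r.stoichiometry]
        if modifiers:
            lst = ET.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for sp_ in dict.fromkeys(modifiers):
                ET.SubElement(lst, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": sp_})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_mathml(_symbolic_rate(r)))

    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def import_sbml(source: str | Path) -> ReactionNetwork:
    """Rebuild a network from a document produced by :func:`export_sbml`."""
    text = (Path(source).read_text() if isinstance(source, Path)
            else source)
    root = ET.fromstring(text)
    payload = root.find(
        f"{{{SBML_NS}}}model/{{{SBML_NS}}}annotation/"
        f"{{{ANNOTATION_NS}}}network")
    if payload is None or not payload.text:
        raise ValueError("document lacks the network serialization "
                         "annotation; cannot round-trip")
    return ReactionNetwork.from_dict(json.loads(payload.text))


def validate_sbml(text: str) -> list[str]:
    """Structural validation: well-formedness plus required SBML attributes.

    Returns a list of problems (empty = valid).  This is a schema-shaped
    check, not a full libsbml consistency validation.
    """
    problems: list[str] = []
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != f"{{{SBML_NS}}}sbml":
        problems.append(f"root element is {root.tag}, expected sbml")
    if root.get("level") != "3":
        problems.append("missing/incorrect level attribute")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        return problems + ["missing model element"]
    ids = set()
    for s in model.iter(f"{{{SBML_NS}}}species"):
        sid = s.get("id")
        if not sid:
            problems.append("species without id")
        elif sid in ids:
            problems.append(f"duplicate species id {sid}")
        ids.add(sid)
        for attr in ("compartment", "boundaryCondition", "constant"):
            if s.get(attr) is None:
                problems.append(f"species {sid}: missing {attr}")
    for r in model.iter(f"{{{SBML_NS}}}reaction"):
        rid = r.get("id")
        if not rid:
            problems.append("reaction without id")
        if r.get("reversible") is None:
            problems.append(f"reaction {rid}: missing reversible")
        for ref in r.iter(f"{{{SBML_NS}}}speciesReference"):
            if ref.get("species") not in ids:
                problems.append(
                    f"reaction {rid}: unknown species "
                    f"{ref.get('species')!r}")
        if r.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math") is None:
            problems.append(f"reaction {rid}: missing kinetic law math")
    return problems
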