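"""SBML Level 3 Core export/import for mass-action networks.

This is a deliberate mass-action subset of SBML L3 Core: one compartment,
one SBML species per :class:`~cisapop.network.SpeciesDef` (constant
species are marked ``constant`` + ``boundaryCondition``), one global
parameter per rate constant, and one irreversible SBML reaction per
:class:`~cisapop.network.ReactionStep` with catalysts as modifiers and an
explicit mass-action MathML kinetic law

    k * reactant1^nu1 * ... * modifier1 * ...

Names that are not valid SBML identifiers (``Casp3*``, ``k12-``,
``Ca2+`` ...) are escaped deterministically; the original name travels in
the ``name`` attribute and in which form round-trips exactly, so
export -> import reproduces the network (and therefore its compiled
right-hand side) bit for bit up to floating-point printing.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Optional, Union

from .errors import NetworkError
from .network import (
    RateConstantSet,
    ReactionNetwork,
    ReactionStep,
    SpeciesDef,
    validate_network,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://cisapop.invalid/sbml-annotations"

_ESCAPES = {"*": "_ast", "+": "_pl", "-": "_mi", ".": "_dot", " ": "_sp"}


def sanitize_id(name: str) -> str:
    """Deterministically escape a name into a valid SBML SId."""
    out = []
    for ch in name:
        if ch.isalnum() or ch == "_":
            out.append(ch)
        elif ch in _ESCAPES:
            out.append(_ESCAPES[ch])
        else:
            out.append(f"_x{ord(ch):04X}")
    sid = "".join(out)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "s_" + sid
    return sid


def _unique_ids(names, label: str) -> Dict[str, str]:
    mapping = {}
    seen = {}
    for name in names:
        sid = sanitize_id(name)
        if sid in seen and seen[sid] != name:
            raise NetworkError(
                f"{label} names {seen[sid]!r} and {name!r} collide on SBML id {sid!r}"
            )
        seen[sid] = name
        mapping[name] = sid
    return mapping


def export_sbml(
    network: ReactionNetwork,
    path: Optional[Union[str, Path]] = None,
    model_id: str = "model",
) -> str:
    """Serialise a validated network as an SBML L3 document string."""
    report = validate_network(network)
    if report:
        raise NetworkError("cannot export invalid network:\n  " + "\n  ".join(report))

    sp_ids = _unique_ids([s.name for s in network.species], "species")
    par_ids = _unique_ids(network.parameters.values, "parameter")
    rxn_ids = _unique_ids([r.id for r in network.reactions], "reaction")

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("cis", ANNOT_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": sanitize_id(model_id)})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": "cell", "size": "1", "spatialDimensions": "3", "constant": "true"},
    )

    if network.species:
        losp = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
        for s in network.species:
            is_const = s.role == "constant"
            ET.SubElement(
                losp,
                f"{{{SBML_NS}}}species",
                {
                    "id": sp_ids[s.name],
                    "name": s.name,
                    "compartment": "cell",
                    "initialConcentration": repr(float(s.initial_value)),
                    "hasOnlySubstanceUnits": "false",
                    "boundaryCondition": "true" if is_const else "false",
                    "constant": "true" if is_const else "false",
                    f"{{{ANNOT_NS}}}pathway": s.pathway_tag,
                },
            )

    if network.parameters.values:
        lop = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
        for kid in network.parameters.values:
            ET.SubElement(
                lop,
                f"{{{SBML_NS}}}parameter",
                {
                    "id": par_ids[kid],
                    "name": kid,
                    "value": repr(float(network.parameters[kid])),
                    "constant": "true",
                },
            )

    if network.reactions:
        lor = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
        for r in network.reactions:
            rx = ET.SubElement(
                lor,
                f"{{{SBML_NS}}}reaction",
                {"id": rxn_ids[r.id], "name": r.id, "reversible": "false"},
            )
            if r.consumed:
                lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
                for name, nu in r.consumed.items():
                    ET.SubElement(
                        lo,
                        f"{{{SBML_NS}}}speciesReference",
                        {
                            "species": sp_ids[name],
                            "stoichiometry": str(int(nu)),
                            "constant": "true",
                        },
                    )
            if r.produced:
                lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
                for name, nu in r.produced.items():
                    ET.SubElement(
                        lo,
                        f"{{{SBML_NS}}}speciesReference",
                        {
                            "species": sp_ids[name],
                            "stoichiometry": str(int(nu)),
                            "constant": "true",
                        },
                    )
            if r.catalysts:
                lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
                for name in sorted(r.catalysts):
                    ET.SubElement(
                        lo,
                        f"{{{SBML_NS}}}modifierSpeciesReference",
                        {"species": sp_ids[name]},
                    )
            law = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
            math = ET.SubElement(law, f"{{{MATHML_NS}}}math")
            times = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
            ET.SubElement(times, f"{{{MATHML_NS}}}times")
            ci = ET.SubElement(times, f"{{{MATHML_NS}}}ci")
            ci.text = par_ids[r.rate_constant_id]
            for name, nu in r.consumed.items():
                if int(nu) == 1:
                    ci = ET.SubElement(times, f"{{{MATHML_NS}}}ci")
                    ci.text = sp_ids[name]
                else:
                    power = ET.SubElement(times, f"{{{MATHML_NS}}}apply")
                    ET.SubElement(power, f"{{{MATHML_NS}}}power")
                    ci = ET.SubElement(power, f"{{{MATHML_NS}}}ci")
                    ci.text = sp_ids[name]
                    cn = ET.SubElement(
                        power, f"{{{MATHML_NS}}}cn", {"type": "integer"}
                    )
                    cn.text = str(int(nu))
            for name in sorted(r.catalysts):
                ci = ET.SubElement(times, f"{{{MATHML_NS}}}ci")
                ci.text = sp_ids[name]

    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def import_sbml(source: Union[str, Path]) -> ReactionNetwork:
    """Parse an SBML document produced by :func:`export_sbml` (or any
    document restricted to the same mass-action subset) back into a
    :class:`ReactionNetwork`."""
    text = str(source)
    if "\n" not in text:
        try:
            path = Path(text)
            if path.exists():
                text = path.read_text()
        except OSError:
            pass
    root = ET.fromstring(text)
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise NetworkError("SBML document has no <model> element")

    sid_to_name: Dict[str, str] = {}
    species: List[SpeciesDef] = []
    for el in model.iterfind(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        sid = el.get("id")
        name = el.get("name") or sid
        sid_to_name[sid] = name
        species.append(
            SpeciesDef(
                name=name,
                role="constant" if el.get("constant") == "true" else "dynamic",
                initial_value=float(el.get("initialConcentration", "0")),
                pathway_tag=el.get(f"{{{ANNOT_NS}}}pathway", "shared"),
            )
        )

    par_to_name: Dict[str, str] = {}
    params: Dict[str, float] = {}
    for el in model.iterfind(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        pid = el.get("id")
        name = el.get("name") or pid
        par_to_name[pid] = name
        params[name] = float(el.get("value", "0"))

    reactions: List[ReactionStep] = []
    for el in model.iterfind(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        consumed: Dict[str, int] = {}
        produced: Dict[str, int] = {}
        for ref in el.iterfind(
            f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"
        ):
            consumed[sid_to_name[ref.get("species")]] = int(
                float(ref.get("stoichiometry", "1"))
            )
        for ref in el.iterfind(
            f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"
        ):
            produced[sid_to_name[ref.get("species")]] = int(
                float(ref.get("stoichiometry", "1"))
            )
        catalysts = frozenset(
            sid_to_name[ref.get("species")]
            for ref in el.iterfind(
                f"{{{SBML_NS}}}listOfModifiers/{{{SBML_NS}}}modifierSpeciesReference"
            )
        )
        rate_id = None
        for ci in el.iterfind(f".//{{{MATHML_NS}}}ci"):
            token = (ci.text or "").strip()
            if token in par_to_name:
                rate_id = par_to_name[token]
                break
        if rate_id is None:
            raise NetworkError(
                f"reaction {el.get('id')!r}: kinetic law references no "
                "known rate constant"
            )
        reactions.append(
            ReactionStep(
                id=el.get("name") or el.get("id"),
                consumed=consumed,
                produced=produced,
                catalysts=catalysts,
                rate_constant_id=rate_id,
            )
        )

    network = ReactionNetwork(
        species=tuple(species),
        reactions=tuple(reactions),
        parameters=RateConstantSet(params),
    )
    report = validate_network(network)
    if report:
        raise NetworkError(
            "imported SBML yields an invalid network:\n  " + "\n  ".join(report)
        )
    return network
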