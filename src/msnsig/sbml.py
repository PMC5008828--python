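"""SBML Level 3 export / import of mass-action networks.

Writes SBML Level 3 Version 1 core with one well-mixed compartment; every
reaction carries an explicit mass-action kinetic law (kf*reactants -
kr*products) with local parameters ``kf`` and ``kr``.  Clamped inputs are
boundary-condition species.  Compartment tags, conserved moieties and
parameter provenance are preserved in a package annotation namespace so a
write/read round trip reproduces the model exactly.

The reader accepts Level 2 or Level 3 documents restricted to this
mass-action subset (uni/bimolecular reactions with kf/kr local parameters or
a recognizable mass-action kinetic law).
"""

from __future__ import annotations

from lxml import etree

from .network import ConservedMoiety, MassActionReaction, NetworkModel, SpeciesDef

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://msnsig.invalid/sbml-annotations"

__all__ = ["write_sbml", "read_sbml", "to_sbml_string", "from_sbml_string"]


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def to_sbml_string(model: NetworkModel) -> bytes:
    model.validate()
    nsmap = {None: SBML_NS, "mn": ANNOT_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap, level="3", version="1")
    mdl = etree.SubElement(root, _q("model"), id=model.name)

    annot = etree.SubElement(mdl, _q("annotation"))
    meta = etree.SubElement(annot, _q("meta", ANNOT_NS))
    for m in model.conserved_moieties:
        etree.SubElement(
            meta,
            _q("moiety", ANNOT_NS),
            name=m.name,
            members=" ".join(m.members),
            total=repr(float(m.total)),
        )
    for key, note in sorted(model.provenance.items()):
        etree.SubElement(meta, _q("provenance", ANNOT_NS), parameter=key, note=note)

    comps = etree.SubElement(mdl, _q("listOfCompartments"))
    etree.SubElement(
        comps, _q("compartment"), id="cell", size="1", spatialDimensions="3",
        constant="true",
    )

    sps = etree.SubElement(mdl, _q("listOfSpecies"))
    for s in model.species:
        el = etree.SubElement(
            sps,
            _q("species"),
            id=s.name,
            compartment="cell",
            initialConcentration=repr(float(s.initial_concentration)),
            boundaryCondition="true" if s.is_clamped_input else "false",
            constant="false",
            hasOnlySubstanceUnits="false",
        )
        el.set(_q("tag", ANNOT_NS), s.compartment_tag)

    rxns = etree.SubElement(mdl, _q("listOfReactions"))
    for r in model.reactions:
        el = etree.SubElement(
            rxns,
            _q("reaction"),
            id=r.id,
            reversible="true" if r.reversible else "false",
        )
        if r.reactants:
            lst = etree.SubElement(el, _q("listOfReactants"))
            for name, stoich in r.reactants:
                etree.SubElement(
                    lst, _q("speciesReference"), species=name,
                    stoichiometry=str(stoich), constant="true",
                )
        if r.products:
            lst = etree.SubElement(el, _q("listOfProducts"))
            for name, stoich in r.products:
                etree.SubElement(
                    lst, _q("speciesReference"), species=name,
                    stoichiometry=str(stoich), constant="true",
                )
        kl = etree.SubElement(el, _q("kineticLaw"))
        math = etree.SubElement(kl, _q("math", MATHML_NS))
        math.append(_mass_action_math(r))
        lps = etree.SubElement(kl, _q("listOfLocalParameters"))
        etree.SubElement(lps, _q("localParameter"), id="kf", value=repr(float(r.kf)))
        etree.SubElement(lps, _q("localParameter"), id="kr", value=repr(float(r.kr)))
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _mass_action_math(r: MassActionReaction) -> etree._Element:
    def product_term(const: str, pairs) -> etree._Element:
        times = etree.Element(_q("apply", MATHML_NS))
        etree.SubElement(times, _q("times", MATHML_NS))
        ci = etree.SubElement(times, _q("ci", MATHML_NS))
        ci.text = const
        for name, stoich in pairs:
            for _ in range(stoich):
                ci = etree.SubElement(times, _q("ci", MATHML_NS))
                ci.text = name
        return times

    fwd = product_term("kf", r.reactants)
    if not r.reversible:
        return fwd
    minus = etree.Element(_q("apply", MATHML_NS))
    etree.SubElement(minus, _q("minus", MATHML_NS))
    minus.append(fwd)
    minus.append(product_term("kr", r.products))
    return minus


def write_sbml(model: NetworkModel, path) -> None:
    with open(path, "wb") as fh:
        fh.write(to_sbml_string(model))


def from_sbml_string(data: bytes | str) -> NetworkModel:
    if isinstance(data, str):
        data = data.encode()
    root = etree.fromstring(data)
    mdl = next(el for el in root if _local(el.tag) == "model")
    model = NetworkModel(name=mdl.get("id", "model"))

    for el in mdl.iter():
        tag = _local(el.tag)
        if tag == "species":
            model.species.append(
                SpeciesDef(
                    name=el.get("id"),
                    compartment_tag=el.get(_q("tag", ANNOT_NS), "cytosol"),
                    initial_concentration=float(el.get("initialConcentration", 0.0)),
                    is_clamped_input=el.get("boundaryCondition", "false") == "true",
                )
            )
        elif tag == "reaction":
            model.reactions.append(_read_reaction(el))
        elif tag == "moiety":
            model.conserved_moieties.append(
                ConservedMoiety(
                    name=el.get("name"),
                    members=el.get("members").split(),
                    total=float(el.get("total")),
                )
            )
        elif tag == "provenance":
            model.provenance[el.get("parameter")] = el.get("note")
    model.validate()
    return model


def _read_reaction(el) -> MassActionReaction:
    reactants: list[tuple[str, int]] = []
    products: list[tuple[str, int]] = []
    kf = kr = None
    for child in el:
        tag = _local(child.tag)
        if tag in ("listOfReactants", "listOfProducts"):
            target = reactants if tag == "listOfReactants" else products
            for ref in child:
                if _local(ref.tag) != "speciesReference":
                    continue
                stoich = int(float(ref.get("stoichiometry", "1")))
                target.append((ref.get("species"), stoich))
        elif tag == "kineticLaw":
            for sub in child.iter():
                if _local(sub.tag) in ("localParameter", "parameter"):
                    if sub.get("id") == "kf":
                        kf = float(sub.get("value"))
                    elif sub.get("id") == "kr":
                        kr = float(sub.get("value"))
    if kf is None:
        raise ValueError(
            f"reaction {el.get('id')!r}: no mass-action kf local parameter found"
        )
    return MassActionReaction(
        id=el.get("id"),
        reactants=reactants,
        products=products,
        kf=kf,
        kr=0.0 if kr is None else kr,
    )


def read_sbml(path) -> NetworkModel:
    with open(path, "rb") as fh:
        return from_sbml_string(fh.read())
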