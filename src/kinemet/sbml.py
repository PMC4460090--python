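"""SBML Level 2 Version 4 import/export with MIRIAM-style annotations.

Models are written as plain SBML L2V4 (the CellDesigner-4.2-era dialect):
each reaction's kinetic law is MathML for one of the three supported rate
forms, with V (and Km) as local reaction parameters, so the documents are
self-contained and round-trip bit-for-bit onto the in-memory types.  On
read, CellDesigner extension subtrees (or any unknown namespace) carry no
kinetic content in scope and are ignored; kinetic laws outside the three
supported forms are rejected with the offending reaction named.
Annotations are emitted as RDF resource URIs per the MIRIAM guidelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import libsbml
import sympy

from .core import (
    Compartment,
    Model,
    ModelError,
    RateLaw,
    Reaction,
    Species,
    validate_model,
)

__all__ = [
    "AnnotationEntry",
    "SBMLReadError",
    "UnsupportedRateLawError",
    "read_sbml",
    "read_sbml_file",
    "write_sbml",
    "write_sbml_file",
    "read_annotations",
]

_KIND_MAP = {
    "mitochondrion": "mitochondrion",
    "inner_membrane": "inner_membrane",
    "intermembrane_space": "intermembrane_space",
    "outer_membrane": "outer_membrane",
    "default": "default",
}


class SBMLReadError(ValueError):
    """Malformed XML or non-SBML input."""


class UnsupportedRateLawError(SBMLReadError):
    """Kinetic law outside the saturation/mass-action/constant family."""


@dataclass
class AnnotationEntry:
    """MIRIAM-style annotation: resource URIs attached to a model entity."""

    entity_id: str
    uris: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        self.uris = tuple(self.uris)
        for uri in self.uris:
            if "://" not in uri and not uri.startswith("urn:"):
                raise ValueError(f"annotation URI {uri!r} is not well-formed")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _rate_law_math(rxn: Reaction) -> str:
    law = rxn.rate_law
    if law.kind == "constant":
        return "V"
    if law.kind == "saturation":
        (s,) = law.substrate_ids
        return f"V * {s} / (Km + {s})"
    return " * ".join(["V", *law.substrate_ids])


def write_sbml(model: Model, annotations: Sequence[AnnotationEntry] = ()) -> str:
    """Serialize a model to an SBML L2V4 document string.

    Refuses (raising :class:`~kinemet.core.ModelError` carrying the report)
    if the model does not validate.
    """
    report = validate_model(model)
    if report:
        raise ModelError("model does not validate:\n" + "\n".join(report))
    doc = libsbml.SBMLDocument(2, 4)
    m = doc.createModel()
    m.setId(model.id or "model")
    if model.name:
        m.setName(model.name)
    if model.notes:
        m.setNotes(
            f"<notes><body xmlns='http://www.w3.org/1999/xhtml'><p>{model.notes}</p>"
            "</body></notes>"
        )
    compartments = model.compartments or [Compartment("default")]
    for c in compartments:
        sc = m.createCompartment()
        sc.setId(c.id)
        if c.name:
            sc.setName(c.name)
        sc.setSize(c.volume)
        sc.setConstant(True)
    ann_by_id = {a.entity_id: a for a in annotations}
    for s in model.species:
        ss = m.createSpecies()
        ss.setId(s.id)
        if s.name:
            ss.setName(s.name)
        ss.setCompartment(s.compartment if model.compartments else "default")
        ss.setInitialConcentration(s.initial_concentration)
        ss.setBoundaryCondition(s.boundary)
        # species role rides in an SBO-less note-free way: sboTerm is too
        # narrow, so the role is carried in the species notes body
        ss.setNotes(
            f"<notes><body xmlns='http://www.w3.org/1999/xhtml'><p>role: {s.role}"
            "</p></body></notes>"
        )
        _attach_annotation(ss, ann_by_id.get(s.id))
    for rxn in model.reactions:
        sr = m.createReaction()
        sr.setId(rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.reversible)
        for sid, n in rxn.reactants:
            ref = sr.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(n))
        for sid, n in rxn.products:
            ref = sr.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(n))
        for sid in rxn.modifiers:
            ref = sr.createModifier()
            ref.setSpecies(sid)
        kl = sr.createKineticLaw()
        pv = kl.createParameter()
        pv.setId("V")
        pv.setValue(rxn.rate_law.V)
        if rxn.rate_law.kind == "saturation":
            pk = kl.createParameter()
            pk.setId("Km")
            pk.setValue(rxn.rate_law.Km)
        ast = libsbml.parseL3Formula(_rate_law_math(rxn))
        kl.setMath(ast)
        _attach_annotation(sr, ann_by_id.get(rxn.id))
    return libsbml.writeSBMLToString(doc)


def _attach_annotation(entity, ann: AnnotationEntry | None) -> None:
    if ann is None:
        return
    entity.setMetaId(f"meta_{ann.entity_id}")
    for uri in ann.uris:
        term = libsbml.CVTerm()
        term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
        term.setBiologicalQualifierType(libsbml.BQB_IS)
        term.addResource(uri)
        entity.addCVTerm(term)


def write_sbml_file(model: Model, path, annotations: Sequence[AnnotationEntry] = ()) -> None:
    with open(path, "w") as fh:
        fh.write(write_sbml(model, annotations))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_sbml(text: str) -> Model:
    """Parse an SBML Level 2/3 document into a :class:`Model`.

    Kinetic-law MathML is pattern-matched onto the three supported rate
    kinds; anything else raises :class:`UnsupportedRateLawError` naming the
    reaction.  CellDesigner extension elements are ignored without error;
    the SBML ``boundaryCondition`` flag maps to ``Species.boundary``.
    """
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLReadError("cannot parse SBML document: " + "; ".join(msgs))
    m = doc.getModel()
    if m is None:
        raise SBMLReadError("document contains no SBML model")
    model = Model(id=m.getId() or "model", name=m.getName() or "",
                  notes=_notes_text(m))
    for i in range(m.getNumCompartments()):
        c = m.getCompartment(i)
        vol = c.getSize() if c.isSetSize() else 1.0
        model.compartments.append(
            Compartment(c.getId(), c.getName() or "", _infer_kind(c), vol)
        )
    for i in range(m.getNumSpecies()):
        s = m.getSpecies(i)
        conc = 0.0
        if s.isSetInitialConcentration():
            conc = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            conc = s.getInitialAmount()
        model.species.append(
            Species(
                id=s.getId(),
                name=s.getName() or "",
                compartment=s.getCompartment() or "default",
                initial_concentration=conc,
                role=_role_from_notes(s),
                boundary=s.getBoundaryCondition(),
            )
        )
    species_ids = set(model.species_ids)
    for i in range(m.getNumReactions()):
        r = m.getReaction(i)
        reactants = tuple(
            (r.getReactant(k).getSpecies(), int(round(r.getReactant(k).getStoichiometry())))
            for k in range(r.getNumReactants())
        )
        products = tuple(
            (r.getProduct(k).getSpecies(), int(round(r.getProduct(k).getStoichiometry())))
            for k in range(r.getNumProducts())
        )
        modifiers = tuple(
            r.getModifier(k).getSpecies() for k in range(r.getNumModifiers())
        )
        law = _parse_kinetic_law(r, species_ids)
        model.reactions.append(
            Reaction(
                id=r.getId(),
                reactants=reactants,
                products=products,
                modifiers=modifiers,
                rate_law=law,
                reversible=r.getReversible(),
                name=r.getName() or "",
            )
        )
    return model


def _infer_kind(c) -> str:
    """Map a compartment name onto the four mitochondrial kinds."""
    tokens = set((c.getName() or c.getId()).lower().replace("-", " ").split())
    if "membrane" in tokens:
        if "inner" in tokens:
            return "inner_membrane"
        if "outer" in tokens:
            return "outer_membrane"
        return "default"
    if "intermembrane" in tokens or ("intra" in tokens and "space" in tokens):
        return "intermembrane_space"
    if any(t.startswith("mitochond") for t in tokens):
        return "mitochondrion"
    return "default"


def _notes_text(entity) -> str:
    if not entity.isSetNotes():
        return ""
    text = entity.getNotesString()
    if "<p>" in text:
        return text.split("<p>", 1)[1].split("</p>", 1)[0].strip()
    return ""


def _role_from_notes(s) -> str:
    if s.isSetNotes():
        text = s.getNotesString()
        if "role:" in text:
            role = text.split("role:", 1)[1].split("<", 1)[0].strip()
            if role:
                return role
    return "metabolite"


def _parse_kinetic_law(r, species_ids: set[str]) -> RateLaw:
    kl = r.getKineticLaw()
    if kl is None or kl.getMath() is None:
        raise UnsupportedRateLawError(f"reaction {r.getId()!r} has no kinetic law")
    params: dict[str, float] = {}
    for k in range(kl.getNumParameters()):
        p = kl.getParameter(k)
        params[p.getId()] = p.getValue()
    formula = libsbml.formulaToL3String(kl.getMath())
    try:
        local = {name: sympy.Float(val) for name, val in params.items()}
        syms = {sid: sympy.Symbol(sid) for sid in species_ids}
        expr = sympy.sympify(formula.replace("^", "**"), locals={**syms, **local})
    except (sympy.SympifyError, TypeError, SyntaxError) as exc:
        raise UnsupportedRateLawError(
            f"reaction {r.getId()!r}: cannot parse kinetic law {formula!r}"
        ) from exc
    return _match_rate_law(r.getId(), expr, species_ids)


def _match_rate_law(rid: str, expr: sympy.Expr, species_ids: set[str]) -> RateLaw:
    """Pattern-match V·x/(Km+x), V·x1·…·xn or V onto :class:`RateLaw`."""
    expr = sympy.cancel(sympy.simplify(expr))
    free = {str(s) for s in expr.free_symbols}
    unknown = free - species_ids
    if unknown:
        raise UnsupportedRateLawError(
            f"reaction {rid!r}: kinetic law references unknown symbols {sorted(unknown)}"
        )
    numer, denom = expr.as_numer_denom()
    if denom.free_symbols:
        # candidate saturation form: numer = V*x, denom = x + Km
        dsyms = list(denom.free_symbols)
        if len(dsyms) != 1:
            raise UnsupportedRateLawError(
                f"reaction {rid!r}: unsupported kinetic law {expr}"
            )
        x = dsyms[0]
        dpoly = sympy.Poly(denom, x)
        npoly = sympy.Poly(numer, x)
        if (
            dpoly.degree() != 1
            or npoly.degree() != 1
            or npoly.coeff_monomial(1).free_symbols
            or float(npoly.coeff_monomial(1)) != 0.0
            or npoly.coeff_monomial(x).free_symbols
            or dpoly.coeff_monomial(1).free_symbols
        ):
            raise UnsupportedRateLawError(
                f"reaction {rid!r}: unsupported kinetic law {expr}"
            )
        lead = float(dpoly.coeff_monomial(x))
        Km = float(dpoly.coeff_monomial(1)) / lead
        V = float(npoly.coeff_monomial(x)) / lead
        if Km <= 0:
            raise UnsupportedRateLawError(
                f"reaction {rid!r}: unsupported kinetic law {expr} (Km <= 0)"
            )
        return RateLaw("saturation", V=V, Km=Km, substrate_ids=(str(x),))
    if not free:
        return RateLaw("constant", V=float(expr))
    # mass action: V * product of species (with multiplicity)
    coeff, rest = expr.as_coeff_Mul()
    factors: list[str] = []
    for base, power in rest.as_powers_dict().items():
        if str(base) not in species_ids or not power.is_Integer or power < 1:
            raise UnsupportedRateLawError(
                f"reaction {rid!r}: unsupported kinetic law {expr}"
            )
        factors.extend([str(base)] * int(power))
    if coeff.free_symbols:
        raise UnsupportedRateLawError(
            f"reaction {rid!r}: unsupported kinetic law {expr}"
        )
    return RateLaw("mass_action", V=float(coeff), substrate_ids=tuple(sorted(factors)))


def read_sbml_file(path) -> Model:
    with open(path) as fh:
        return read_sbml(fh.read())


def read_annotations(text: str) -> list[AnnotationEntry]:
    """Extract MIRIAM resource URIs from an SBML document."""
    doc = libsbml.readSBMLFromString(text)
    m = doc.getModel()
    if m is None:
        raise SBMLReadError("document contains no SBML model")
    out: list[AnnotationEntry] = []
    entities: list = [m.getSpecies(i) for i in range(m.getNumSpecies())]
    entities += [m.getReaction(i) for i in range(m.getNumReactions())]
    for e in entities:
        uris = []
        for t in range(e.getNumCVTerms()):
            term = e.getCVTerm(t)
            for u in range(term.getNumResources()):
                uris.append(term.getResourceURI(u))
        if uris:
            out.append(AnnotationEntry(e.getId(), tuple(uris)))
    return out
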