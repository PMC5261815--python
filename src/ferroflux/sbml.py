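"""SBML Level 3 export/import of the whole-body model.

The document lists the 20 species with their initial amounts, every model
constant as an SBML parameter, and the iron/expression/signaling fluxes as
reactions with content-MathML kinetic laws (Level 3 Version 2, whose core
MathML subset includes ``min`` for the ferritin storage cap).  Serialization
is fully deterministic, so export -> import -> export is byte-stable.

Identifier conventions (the documented naming table):

* species ids are the canonical state names (``Fe_serum`` ... ``STAT3p``);
* kinetic parameters keep their :data:`~ferroflux.params.KINETIC_PARAM_NAMES`
  ids; structural constants are ``Fe_food``, ``s_LPS``, ``K_SMAD`` and the
  promoter weights prefixed ``prom_`` (e.g. ``prom_q_S``);
* reaction ids name the flux (``import_liver``, ``export_duodenum``,
  ``fpn_translation_spleen``, ``hepcidin_synthesis``, ...).

The importer trusts the documented reaction set: it validates ids and reads
parameter values and initial amounts; it does not re-derive rate laws from
arbitrary MathML.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .model import N_STATES, STATE_NAMES
from .params import KINETIC_PARAM_NAMES, ParameterSet, PromoterParams

__all__ = ["export_sbml", "import_sbml", "REACTION_IDS"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_PROMOTER_FIELDS = ("q_S", "q_T", "w_S", "w_T", "w_ST", "omega")
_STRUCTURAL = ("Fe_food", "s_LPS", "K_SMAD", "Tf_cap")


# ---------------------------------------------------------------------------
# tiny content-MathML expression builders
# ---------------------------------------------------------------------------

def _ci(name: str) -> ET.Element:
    e = ET.Element("ci")
    e.text = f" {name} "
    return e


def _apply(op: str, *args: ET.Element) -> ET.Element:
    a = ET.Element("apply")
    a.append(ET.Element(op))
    for x in args:
        a.append(x)
    return a


def _times(*args): return _apply("times", *args)
def _plus(*args): return _apply("plus", *args)
def _divide(n, d): return _apply("divide", n, d)
def _min(*args): return _apply("min", *args)
def _sq(x):
    e = ET.Element("cn"); e.set("type", "integer"); e.text = " 2 "
    return _apply("power", x, e)


def _mm(vmax: str, sub: str, km: str) -> ET.Element:
    """vmax * sub / (km + sub)"""
    return _divide(_times(_ci(vmax), _ci(sub)), _plus(_ci(km), _ci(sub)))


def _math(expr: ET.Element) -> ET.Element:
    m = ET.Element("math")
    m.set("xmlns", _MATHML_NS)
    m.append(expr)
    return m


def _promoter_math() -> ET.Element:
    """s_hep * (1 + w_S q_S S + w_T q_T T + w_ST omega q_S q_T S T)
             / (1 + q_S S + q_T T + omega q_S q_T S T),
    with S = BMP6/(K_SMAD + BMP6) and T = STAT3p."""
    one = ET.Element("cn"); one.set("type", "integer"); one.text = " 1 "
    one2 = ET.Element("cn"); one2.set("type", "integer"); one2.text = " 1 "

    def S(): return _divide(_ci("BMP6"), _plus(_ci("K_SMAD"), _ci("BMP6")))
    def T(): return _ci("STAT3p")
    num = _plus(one,
                _times(_ci("prom_w_S"), _ci("prom_q_S"), S()),
                _times(_ci("prom_w_T"), _ci("prom_q_T"), T()),
                _times(_ci("prom_w_ST"), _ci("prom_omega"), _ci("prom_q_S"),
                       _ci("prom_q_T"), S(), T()))
    den = _plus(one2,
                _times(_ci("prom_q_S"), S()),
                _times(_ci("prom_q_T"), T()),
                _times(_ci("prom_omega"), _ci("prom_q_S"), _ci("prom_q_T"),
                       S(), T()))
    return _times(_ci("s_hep"), _divide(num, den))


def _reactions() -> list[tuple[str, list[str], list[str], ET.Element]]:
    """(id, reactants, products, kinetic-law math) for every flux."""
    rx: list[tuple[str, list[str], list[str], ET.Element]] = []
    rx.append(("uptake_duodenum", [], ["Fe_duodenum"],
               _mm("V_duo", "Fe_food", "K_duo")))
    rx.append(("import_liver", ["Fe_serum"], ["Fe_liver"],
               _plus(_times(_ci("v_liver"), _ci("Fe_serum")),
                     _divide(_times(_ci("v_NTBI"), _sq(_ci("Fe_serum"))),
                             _plus(_ci("K_NTBI"), _ci("Fe_serum"))))))
    for organ, pool in (("spleen", "Fe_spleen"), ("duodenum", "Fe_duodenum"),
                        ("bm", "Fe_bm"), ("other", "Fe_other")):
        rate = {"spleen": "v_spleen", "duodenum": "v_duo", "bm": "v_bm",
                "other": "v_other"}[organ]
        rx.append((f"import_{organ}", ["Fe_serum"], [pool],
                   _times(_ci(rate), _ci("Fe_serum"))))
    rx.append(("export_liver", ["Fe_liver"], ["Fe_serum"],
               _times(_ci("u_liver"), _ci("Fpn_liver"),
                      _min(_ci("Fe_liver"), _ci("Fe_max")))))
    for organ, pool, fpn, u in (("spleen", "Fe_spleen", "Fpn_spleen", "u_spleen"),
                                ("duodenum", "Fe_duodenum", "Fpn_duo", "u_duo"),
                                ("other", "Fe_other", "Fpn_other", "u_other")):
        rx.append((f"export_{organ}", [pool], ["Fe_serum"],
                   _times(_ci(u), _ci(fpn), _ci(pool))))
    rx.append(("erythropoiesis", ["Fe_bm"], ["Fe_RBC"],
               _times(_ci("v_RBC"), _ci("Fe_bm"))))
    rx.append(("ineffective_erythropoiesis", ["Fe_bm"], ["Fe_spleen"],
               _times(_ci("v_splBM"), _ci("Fe_bm"))))
    rx.append(("rbc_recycling", ["Fe_RBC"], ["Fe_spleen"],
               _times(_ci("v_splRBC"), _ci("Fe_RBC"))))
    rx.append(("loss_duodenum", ["Fe_duodenum"], [],
               _times(_ci("l_duo"), _ci("Fe_duodenum"))))
    rx.append(("loss_other", ["Fe_other"], [],
               _times(_ci("l_other"), _ci("Fe_other"))))
    organs = (("liver", "Fe_liver", "a_liver", "b_liver", "k2_liver"),
              ("spleen", "Fe_spleen", "a_spleen", "b_spleen", "k2_spleen"),
              ("duo", "Fe_duodenum", "a_duo", "b_duo", "k2_duo"),
              ("other", "Fe_other", "a_other", "b_other", "k2_rest"))
    for organ, pool, a, b, k2 in organs:
        mrna, fpn = f"FpnmRNA_{organ}", f"Fpn_{organ}"
        rx.append((f"fpn_transcription_{organ}", [], [mrna],
                   _divide(_times(_ci(a), _ci("K_LPS")),
                           _plus(_ci("K_LPS"), _ci("LPS")))))
        rx.append((f"fpn_mrna_decay_{organ}", [mrna], [],
                   _times(_ci("d_mRNA"), _ci(mrna))))
        rx.append((f"fpn_translation_{organ}", [], [fpn],
                   _times(_ci(b),
                          _divide(_ci(pool), _plus(_ci("K_IRE"), _ci(pool))),
                          _ci(mrna))))
        rx.append((f"fpn_degradation_{organ}", [fpn], [],
                   _times(_plus(_ci("k1"), _times(_ci(k2), _ci("Hep"))),
                          _ci(fpn))))
    rx.append(("hepcidin_synthesis", [], ["Hep"], _promoter_math()))
    rx.append(("hepcidin_degradation", ["Hep"], [],
               _times(_ci("d_hep"), _ci("Hep"))))
    rx.append(("bmp6_synthesis", [], ["BMP6"],
               _mm("s_BMP6", "Fe_liver", "K_BMP6")))
    rx.append(("bmp6_decay", ["BMP6"], [],
               _times(_ci("d_BMP6"), _ci("BMP6"))))
    rx.append(("il6_synthesis", [], ["IL6"], _mm("s_IL6", "LPS", "K_IL6")))
    rx.append(("il6_decay", ["IL6"], [], _times(_ci("d_IL6"), _ci("IL6"))))
    rx.append(("lps_source", [], ["LPS"], _ci("s_LPS")))
    rx.append(("lps_decay", ["LPS"], [], _times(_ci("d_LPS"), _ci("LPS"))))
    rx.append(("stat3_activation", [], ["STAT3p"],
               _mm("s_STAT", "IL6", "K_STAT")))
    rx.append(("stat3_deactivation", ["STAT3p"], [],
               _times(_ci("d_STAT"), _ci("STAT3p"))))
    return rx


REACTION_IDS: tuple[str, ...] = tuple(r[0] for r in _reactions())


def _indent(elem: ET.Element, level: int = 0) -> None:
    pad = "\n" + "  " * level
    if len(elem):
        if not elem.text or not elem.text.strip():
            elem.text = pad + "  "
        for child in elem:
            _indent(child, level + 1)
            if not child.tail or not child.tail.strip():
                child.tail = pad + "  "
        if not elem[-1].tail or not elem[-1].tail.strip():
            elem[-1].tail = pad
    elif level and (not elem.tail or not elem.tail.strip()):
        elem.tail = pad


def export_sbml(params: ParameterSet, state0: np.ndarray,
                path: str | Path | None = None) -> str:
    """Serialize the model (parameter values + initial state) to SBML L3V2.

    Returns the document string; optionally also writes it to ``path``.
    """
    state0 = np.asarray(state0, dtype=float)
    if state0.shape != (N_STATES,):
        raise ValueError(f"state0 must have {N_STATES} entries")
    sbml = ET.Element("sbml")
    sbml.set("xmlns", _SBML_NS)
    sbml.set("level", "3")
    sbml.set("version", "2")
    model = ET.SubElement(sbml, "model")
    model.set("id", "whole_body_iron_homeostasis")
    model.set("substanceUnits", "microgram")
    model.set("timeUnits", "hour")

    comps = ET.SubElement(model, "listOfCompartments")
    comp = ET.SubElement(comps, "compartment")
    comp.set("id", "mouse")
    comp.set("size", "1")
    comp.set("constant", "true")

    species = ET.SubElement(model, "listOfSpecies")
    for name, value in zip(STATE_NAMES, state0):
        sp = ET.SubElement(species, "species")
        sp.set("id", name)
        sp.set("compartment", "mouse")
        sp.set("initialAmount", repr(float(value)))
        sp.set("hasOnlySubstanceUnits", "true")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")

    plist = ET.SubElement(model, "listOfParameters")

    def add_param(pid: str, value: float) -> None:
        pe = ET.SubElement(plist, "parameter")
        pe.set("id", pid)
        pe.set("value", repr(float(value)))
        pe.set("constant", "true")

    for name in KINETIC_PARAM_NAMES:
        add_param(name, getattr(params, name))
    for name in _STRUCTURAL:
        add_param(name, getattr(params, name))
    for name in _PROMOTER_FIELDS:
        add_param(f"prom_{name}", getattr(params.promoter, name))

    rlist = ET.SubElement(model, "listOfReactions")
    for rid, reactants, products, math in _reactions():
        re_ = ET.SubElement(rlist, "reaction")
        re_.set("id", rid)
        re_.set("reversible", "false")
        if reactants:
            lor = ET.SubElement(re_, "listOfReactants")
            for sid in reactants:
                sr = ET.SubElement(lor, "speciesReference")
                sr.set("species", sid)
                sr.set("stoichiometry", "1")
                sr.set("constant", "true")
        if products:
            lop = ET.SubElement(re_, "listOfProducts")
            for sid in products:
                sr = ET.SubElement(lop, "speciesReference")
                sr.set("species", sid)
                sr.set("stoichiometry", "1")
                sr.set("constant", "true")
        kl = ET.SubElement(re_, "kineticLaw")
        kl.append(_math(math))

    _indent(sbml)
    doc = ('<?xml version="1.0" encoding="UTF-8"?>\n'
           + ET.tostring(sbml, encoding="unicode") + "\n")
    if path is not None:
        Path(path).write_text(doc)
    return doc


def import_sbml(source: str | Path) -> tuple[ParameterSet, np.ndarray]:
    """Parse an exported document back into (parameters, initial state).

    Raises ``ValueError`` (with the offending id) on unknown species, missing
    parameters or an unexpected species count.
    """
    text = source if isinstance(source, str) and source.lstrip().startswith("<") \
        else Path(source).read_text()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ValueError(f"not a parseable SBML document: {exc}") from exc
    ns = {"s": _SBML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise ValueError("document has no <model> element")
    state0 = np.full(N_STATES, np.nan)
    index = {name: i for i, name in enumerate(STATE_NAMES)}
    species = model.findall("s:listOfSpecies/s:species", ns)
    if len(species) != N_STATES:
        raise ValueError(f"expected {N_STATES} species, found {len(species)}")
    for sp in species:
        sid = sp.get("id")
        if sid not in index:
            raise ValueError(f"unmapped species id {sid!r}")
        state0[index[sid]] = float(sp.get("initialAmount", "nan"))
    if np.any(np.isnan(state0)):
        raise ValueError("species without initialAmount")
    values = {pe.get("id"): float(pe.get("value"))
              for pe in model.findall("s:listOfParameters/s:parameter", ns)}
    missing = [n for n in (*KINETIC_PARAM_NAMES, *_STRUCTURAL) if n not in values]
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    for rx in model.findall("s:listOfReactions/s:reaction", ns):
        if rx.get("id") not in REACTION_IDS:
            raise ValueError(f"unknown reaction id {rx.get('id')!r}")
    prom = PromoterParams(**{f: values[f"prom_{f}"] for f in _PROMOTER_FIELDS})
    kwargs = {n: values[n] for n in KINETIC_PARAM_NAMES}
    kwargs.update({n: values[n] for n in _STRUCTURAL})
    return ParameterSet(promoter=prom, **kwargs), state0
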