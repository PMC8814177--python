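"""Pathway model: domain types, SBML import, adaptation rules and native format.

The simulator consumes a :class:`PathwayModel`: a list of species (metabolites
and enzymes, each with a molecular weight and an initial concentration in
mmol/l) plus a list of enzyme-catalysed reactions with integer stoichiometry,
a turnover number ``kcat`` and a reversibility flag.  Models can be imported
from SBML kinetic models (rate laws are ignored apart from kcat/Km extraction)
and are persisted in a small versioned XML dialect with a YAML mirror.

The adaptation rules mirror how a bulk kinetic model of yeast glycolysis is
turned into a particle model: bulk reactions without an explicit catalysing
enzyme are dropped, fermentation and transport steps are excluded, the three
control points (hexokinase/glucokinase, phosphofructokinase, pyruvate kinase)
are forced irreversible, and concentrations are scaled below a cap so that
the particle counts in an attolitre stay tractable without letting rare
species round down to zero molecules.
"""

from __future__ import annotations

import logging
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .constants import AVOGADRO
from .physics import EnvironmentParams

logger = logging.getLogger(__name__)

FORMAT_NAME = "cytoabm-model"
FORMAT_VERSION = "1"


class ModelError(ValueError):
    """A pathway model violates its invariants."""


class ModelFormatError(ModelError):
    """A native model file cannot be parsed."""


class SBMLParseError(ModelError):
    """An SBML file cannot be parsed."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species.

    ``initial_concentration`` is in mmol/l; ``molecular_weight`` in g/mol.
    ``approx`` marks values that are documented approximations rather than
    numbers taken from a source model.
    """

    id: str
    name: str = ""
    role: str = "metabolite"  # "metabolite" | "enzyme"
    molecular_weight: float = 0.0
    initial_concentration: float = 0.0
    approx: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("metabolite", "enzyme"):
            raise ModelError(f"species {self.id!r}: bad role {self.role!r}")
        if not self.molecular_weight > 0:
            raise ModelError(
                f"species {self.id!r}: molecular_weight must be > 0, "
                f"got {self.molecular_weight}"
            )
        if self.initial_concentration < 0:
            raise ModelError(
                f"species {self.id!r}: negative initial concentration"
            )

    def initial_count(self, volume: float) -> int:
        """Initial particle number at the given volume (litres)."""
        return concentration_to_count(self.initial_concentration, volume)


@dataclass(frozen=True)
class ReactionSpec:
    """One catalysed reaction carried out by a single isoenzyme.

    ``substrates`` and ``products`` are tuples of ``(species_id, stoich)``.
    ``kcat`` is the forward turnover number (1/s); ``kcat_reverse`` defaults
    to the forward value for reversible reactions.  ``km`` maps substrate ids
    to Michaelis constants (mmol/l) and is only needed for the specificity
    (kcat/Km priority) binding mode.
    """

    id: str
    enzyme_species: str | None
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    reversible: bool = False
    kcat: float = 0.0
    kcat_reverse: float | None = None
    km: Mapping[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", tuple(
            (str(s), int(n)) for s, n in self.substrates))
        object.__setattr__(self, "products", tuple(
            (str(s), int(n)) for s, n in self.products))
        object.__setattr__(self, "km", dict(self.km))
        if not self.substrates or not self.products:
            raise ModelError(
                f"reaction {self.id!r}: substrate and product lists "
                "must be non-empty")
        for side in (self.substrates, self.products):
            for sp, n in side:
                if n < 1:
                    raise ModelError(
                        f"reaction {self.id!r}: stoichiometry of {sp!r} "
                        f"must be a positive integer, got {n}")
        if not self.kcat > 0:
            raise ModelError(f"reaction {self.id!r}: kcat must be > 0")
        if self.kcat_reverse is not None and not self.kcat_reverse > 0:
            raise ModelError(f"reaction {self.id!r}: kcat_reverse must be > 0")

    def kcat_for(self, direction: str) -> float:
        if direction == "forward":
            return self.kcat
        return self.kcat_reverse if self.kcat_reverse is not None else self.kcat

    def side(self, direction: str, which: str) -> tuple[tuple[str, int], ...]:
        """Substrates/products of a direction ("forward" consumes substrates)."""
        fwd = direction == "forward"
        if (which == "substrates") == fwd:
            return self.substrates
        return self.products


@dataclass(frozen=True)
class PathwayModel:
    """Species + reactions + environment: the simulator's complete input."""

    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)
    provenance: str = "fixture"

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))

    @property
    def volume(self) -> float:
        """Simulated volume in litres."""
        return self.environment.volume

    def species_by_id(self) -> dict[str, SpeciesSpec]:
        return {s.id: s for s in self.species}

    def reaction_by_id(self) -> dict[str, ReactionSpec]:
        return {r.id: r for r in self.reactions}

    def validate(self, strict: bool = True) -> None:
        """Check referential integrity; with ``strict`` also require every
        reaction to name a catalysing enzyme of role ``enzyme``."""
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelError(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        table = self.species_by_id()
        for r in self.reactions:
            for sp, _ in (*r.substrates, *r.products):
                if sp not in table:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown species {sp!r}")
            if r.enzyme_species is not None and r.enzyme_species not in table:
                raise ModelError(
                    f"reaction {r.id!r} references unknown enzyme "
                    f"{r.enzyme_species!r}")
            if strict:
                if r.enzyme_species is None:
                    raise ModelError(
                        f"reaction {r.id!r} has no catalysing enzyme")
                if table[r.enzyme_species].role != "enzyme":
                    raise ModelError(
                        f"reaction {r.id!r}: enzyme {r.enzyme_species!r} "
                        "does not have role 'enzyme'")


@dataclass(frozen=True)
class ExclusionRules:
    """Name patterns for reactions to drop or force irreversible.

    Patterns are regular expressions matched case-insensitively against the
    reaction id, the reaction name and the catalysing enzyme id.  The default
    set removes adenylate kinase, ATPase, the UDP-to-UTP reaction, glucose
    transport, the pyruvate decarboxylases (PDC1/5/6) and the alcohol
    dehydrogenases (ADH1/5), and makes hexokinase/glucokinase,
    phosphofructokinase and pyruvate kinase irreversible.
    """

    removed_reactions: tuple[str, ...] = ()
    removed_species: tuple[str, ...] = ()
    forced_irreversible: tuple[str, ...] = ()
    drop_enzymeless: bool = True

    @classmethod
    def defaults(cls) -> "ExclusionRules":
        return cls(
            removed_reactions=(
                r"adenylate[ _-]?kinase", r"\bADK1?\b", r"ATPase",
                r"UDP\b.*\bUTP", r"glucose[ _-]?transport", r"\bHXT\d?\b",
                r"\bPDC[156]\b", r"\bADH[15]\b",
                r"pyruvate[ _-]?decarboxylase", r"alcohol[ _-]?dehydrogenase",
            ),
            forced_irreversible=(
                r"hexokinase", r"glucokinase", r"\bHXK\d?\b", r"\bGLK1?\b",
                r"phosphofructokinase", r"\bPFK\d?\b",
                r"pyruvate[ _-]?kinase", r"\bPYK\d?\b", r"\bCDC19\b",
            ),
        )


# --------------------------------------------------------------------------
# Particle-count conversion
# --------------------------------------------------------------------------

def concentration_to_count(c: float, volume: float) -> int:
    """Particles of a species at concentration ``c`` (mmol/l) in ``volume`` (l).

    round(c * 1e-3 * N_A * V), with ties rounded away from zero.
    """
    if c < 0:
        raise ValueError(f"negative concentration: {c}")
    if not volume > 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    x = c * 1e-3 * AVOGADRO * volume
    return int(math.floor(x + 0.5))


def count_to_concentration(n: int, volume: float) -> float:
    """Concentration in mmol/l of ``n`` particles in ``volume`` litres."""
    if n < 0:
        raise ValueError(f"negative count: {n}")
    if not volume > 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return n / (1e-3 * AVOGADRO * volume)


# --------------------------------------------------------------------------
# Adaptation rules
# --------------------------------------------------------------------------

def _matches(rx: re.Pattern, reaction: ReactionSpec) -> bool:
    hay = (reaction.id, reaction.name, reaction.enzyme_species or "")
    return any(rx.search(h) for h in hay)


def apply_exclusions(
    model: PathwayModel,
    rules: ExclusionRules | None = None,
    prune_orphans: bool = True,
) -> PathwayModel:
    """Drop excluded reactions and force the control points irreversible.

    Idempotent.  Patterns that match nothing produce a warning log line (model
    revisions drift), never an error.  Orphan metabolites (referenced by no
    remaining reaction) are pruned when ``prune_orphans`` is set; enzymes are
    kept only if they still catalyse something.
    """
    if rules is None:
        rules = ExclusionRules.defaults()
    removed_rx = [re.compile(p, re.IGNORECASE) for p in rules.removed_reactions]
    irrev_rx = [re.compile(p, re.IGNORECASE) for p in rules.forced_irreversible]
    species_rx = [re.compile(p, re.IGNORECASE) for p in rules.removed_species]

    kept: list[ReactionSpec] = []
    hits = {p: 0 for p in rules.removed_reactions}
    for r in model.reactions:
        drop = False
        for pat, rx in zip(rules.removed_reactions, removed_rx):
            if _matches(rx, r):
                hits[pat] += 1
                drop = True
        if rules.drop_enzymeless and r.enzyme_species is None:
            logger.info("dropping bulk reaction %s (no catalysing enzyme)", r.id)
            drop = True
        if drop:
            continue
        if not r.reversible:
            kept.append(r)
            continue
        if any(_matches(rx, r) for rx in irrev_rx):
            kept.append(replace(r, reversible=False, kcat_reverse=None))
        else:
            kept.append(r)
    for pat, n in hits.items():
        if n == 0:
            logger.warning("exclusion pattern %r matched no reaction", pat)

    used: set[str] = set()
    for r in kept:
        used.update(sp for sp, _ in r.substrates)
        used.update(sp for sp, _ in r.products)
        if r.enzyme_species:
            used.add(r.enzyme_species)
    species = []
    for s in model.species:
        if any(rx.search(s.id) or rx.search(s.name) for rx in species_rx):
            continue
        if prune_orphans and s.id not in used:
            logger.info("pruning orphan species %s", s.id)
            continue
        species.append(s)
    return replace(model, species=tuple(species), reactions=tuple(kept))


def scale_concentrations(
    model: PathwayModel, cap: float = 1.0, margin: float = 0.01
) -> PathwayModel:
    """Scale every initial concentration strictly below ``cap`` (mmol/l).

    All concentrations are divided by a common factor chosen so the largest
    lands just under the cap (order-preserving); any positive species whose
    particle count at the model volume would then round to zero is floored to
    the concentration of exactly one particle, so that rare species do not
    disappear from the particle picture.
    """
    if not cap > 0:
        raise ValueError("cap must be > 0")
    volume = model.volume
    concs = [s.initial_concentration for s in model.species]
    cmax = max(concs, default=0.0)
    factor = max(1.0, cmax / cap * (1.0 + margin))
    floor_c = 1.0 / (1e-3 * AVOGADRO * volume)  # exactly one particle
    if floor_c >= cap:
        raise ModelError(
            f"cannot scale below cap={cap} mmol/l: one particle in "
            f"{volume} l is already {floor_c:.4g} mmol/l")

    already_fine = factor == 1.0 and all(
        c == 0 or concentration_to_count(c, volume) >= 1 for c in concs)
    if already_fine:
        return model

    species = []
    offenders = []
    for s in model.species:
        c = s.initial_concentration / factor
        if s.initial_concentration > 0 and concentration_to_count(c, volume) < 1:
            c = floor_c
        if c >= cap:
            offenders.append(s.id)
        species.append(replace(s, initial_concentration=c))
    if offenders:
        raise ModelError(
            f"species cannot satisfy cap and count>=1 at volume {volume} l: "
            f"{offenders}")
    return replace(model, species=tuple(species))


# --------------------------------------------------------------------------
# SBML import
# --------------------------------------------------------------------------

#: Fallback molecular weights (g/mol) when the source provides none and the
#: bundled table has no entry; flagged approx on the resulting species.
DEFAULT_METABOLITE_WEIGHT = 300.0
DEFAULT_ENZYME_WEIGHT = 50000.0

_KCAT_RE = re.compile(r"kcat|k_cat|turnover", re.IGNORECASE)
_KM_RE = re.compile(r"^k?m[_ ]?(?P<sp>.+)$", re.IGNORECASE)


def _unit_factor_to_mmol_per_l(libsbml_model, units_id: str | None) -> float:
    """Multiplier converting a declared concentration unit to mmol/l.

    Unknown or undeclared units are taken to be mmol/l already (the convention
    of the source models this importer targets)."""
    if not units_id:
        return 1.0
    ud = libsbml_model.getUnitDefinition(units_id)
    if ud is None:
        return 1.0
    mole_factor = None
    for u in ud.getListOfUnits():
        if u.isMole():
            mole_factor = u.getMultiplier() * 10.0 ** u.getScale()
    if mole_factor is None:
        return 1.0
    # mole_factor mol/l  ->  mmol/l
    return mole_factor * 1e3


def parse_sbml(
    path: str | Path,
    weights: Mapping[str, float] | None = None,
    default_kcat: float = 100.0,
) -> PathwayModel:
    """Read an SBML Level 2/3 kinetic model into a :class:`PathwayModel`.

    Enzymes are identified as species listed as reaction modifiers.  Every
    enzyme must carry an initial concentration (the particle picture needs
    explicit enzyme copy numbers); a missing one is a hard error naming the
    species.  Rate laws are not interpreted: only parameters that look like
    kcat (and per-substrate Km) are extracted; reactions without one get
    ``default_kcat`` with a warning.  Molecular weights come from ``weights``,
    then the bundled table, then a role-based default (flagged approx).
    """
    import libsbml  # deferred: optional dependency

    from .data import MOLECULAR_WEIGHTS

    doc = libsbml.readSBML(str(path))
    nerr = doc.getNumErrors()
    fatal = [
        doc.getError(i) for i in range(nerr)
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if fatal:
        e = fatal[0]
        raise SBMLParseError(
            f"{path}: line {e.getLine()}, column {e.getColumn()}: "
            f"{e.getMessage().strip()}")
    sbml = doc.getModel()
    if sbml is None:
        raise SBMLParseError(f"{path}: no model element")

    weights = dict(weights or {})
    modifier_ids: set[str] = set()
    for i in range(sbml.getNumReactions()):
        rxn = sbml.getReaction(i)
        for j in range(rxn.getNumModifiers()):
            modifier_ids.add(rxn.getModifier(j).getSpecies())

    species: list[SpeciesSpec] = []
    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        sid = sp.getId()
        role = "enzyme" if sid in modifier_ids else "metabolite"
        conc = None
        if sp.isSetInitialConcentration():
            factor = _unit_factor_to_mmol_per_l(
                sbml, sp.getSubstanceUnits() or sbml.getSubstanceUnits())
            conc = sp.getInitialConcentration() * factor
        elif sp.isSetInitialAmount():
            comp = sbml.getCompartment(sp.getCompartment())
            vol = comp.getSize() if comp and comp.isSetSize() else 1.0
            conc = sp.getInitialAmount() / vol * 1e3  # mol/l -> mmol/l
        if conc is None:
            if role == "enzyme":
                raise ModelError(
                    f"enzyme species {sid!r} has no initial concentration; "
                    "enzyme copy numbers are required to instantiate agents")
            logger.warning("species %s has no initial concentration; using 0",
                           sid)
            conc = 0.0
        name = sp.getName() or sid
        approx = False
        mw = weights.get(sid) or weights.get(name)
        if mw is None:
            mw = MOLECULAR_WEIGHTS.get(sid.upper()) or MOLECULAR_WEIGHTS.get(
                name.upper())
        if mw is None:
            mw = (DEFAULT_ENZYME_WEIGHT if role == "enzyme"
                  else DEFAULT_METABOLITE_WEIGHT)
            approx = True
            logger.warning("no molecular weight for %s; using %s g/mol",
                           sid, mw)
        species.append(SpeciesSpec(
            id=sid, name=name, role=role, molecular_weight=float(mw),
            initial_concentration=float(conc), approx=approx))

    reactions: list[ReactionSpec] = []
    for i in range(sbml.getNumReactions()):
        rxn = sbml.getReaction(i)
        subs = tuple(
            (rxn.getReactant(j).getSpecies(),
             max(1, int(round(rxn.getReactant(j).getStoichiometry() or 1))))
            for j in range(rxn.getNumReactants()))
        prods = tuple(
            (rxn.getProduct(j).getSpecies(),
             max(1, int(round(rxn.getProduct(j).getStoichiometry() or 1))))
            for j in range(rxn.getNumProducts()))
        if not subs or not prods:
            logger.warning(
                "skipping boundary reaction %s (empty substrate or product "
                "side)", rxn.getId())
            continue
        enzyme = rxn.getModifier(0).getSpecies() if rxn.getNumModifiers() else None
        kcat = None
        km: dict[str, float] = {}
        klaw = rxn.getKineticLaw()
        if klaw is not None:
            params = [klaw.getParameter(j)
                      for j in range(klaw.getNumParameters())]
            if klaw.getNumLocalParameters():
                params += [klaw.getLocalParameter(j)
                           for j in range(klaw.getNumLocalParameters())]
            for p in params:
                pid = p.getId() or p.getName()
                if _KCAT_RE.search(pid) and kcat is None:
                    kcat = p.getValue()
                else:
                    m = _KM_RE.match(pid)
                    if m:
                        km[m.group("sp")] = p.getValue()
        if kcat is None or not kcat > 0:
            logger.warning("reaction %s: no kcat parameter found; using "
                           "default %s 1/s", rxn.getId(), default_kcat)
            kcat = default_kcat
        reactions.append(ReactionSpec(
            id=rxn.getId(), name=rxn.getName() or rxn.getId(),
            enzyme_species=enzyme, substrates=subs, products=prods,
            reversible=bool(rxn.getReversible()), kcat=float(kcat), km=km))

    model = PathwayModel(
        species=tuple(species), reactions=tuple(reactions),
        provenance=sbml.getId() or str(path))
    model.validate(strict=False)
    return model


# --------------------------------------------------------------------------
# Native format (versioned XML, YAML mirror)
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(x, ".17g")


def _model_to_dict(model: PathwayModel) -> dict:
    env = model.environment
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "provenance": model.provenance,
        "environment": {
            "temperature": env.temperature, "viscosity": env.viscosity,
            "tick": env.tick, "side": env.side,
        },
        "species": [
            {
                "id": s.id, "name": s.name, "role": s.role,
                "molecular_weight": s.molecular_weight,
                "initial_concentration": s.initial_concentration,
                "approx": s.approx,
            }
            for s in model.species
        ],
        "reactions": [
            {
                "id": r.id, "name": r.name, "enzyme": r.enzyme_species,
                "reversible": r.reversible, "kcat": r.kcat,
                **({"kcat_reverse": r.kcat_reverse}
                   if r.kcat_reverse is not None else {}),
                "substrates": [
                    {"species": sp, "stoichiometry": n}
                    for sp, n in r.substrates],
                "products": [
                    {"species": sp, "stoichiometry": n}
                    for sp, n in r.products],
                **({"km": dict(r.km)} if r.km else {}),
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(d: dict, where: str = "<dict>") -> PathwayModel:
    if d.get("format") != FORMAT_NAME:
        raise ModelFormatError(f"{where}: not a {FORMAT_NAME} document")
    if str(d.get("version")) != FORMAT_VERSION:
        raise ModelFormatError(
            f"{where}: unknown schema version {d.get('version')!r} "
            f"(this build reads version {FORMAT_VERSION})")
    try:
        env = EnvironmentParams(**{
            k: float(v) for k, v in d["environment"].items()})
        species = tuple(
            SpeciesSpec(
                id=s["id"], name=s.get("name", ""), role=s["role"],
                molecular_weight=float(s["molecular_weight"]),
                initial_concentration=float(s["initial_concentration"]),
                approx=bool(s.get("approx", False)))
            for s in d["species"])
        reactions = tuple(
            ReactionSpec(
                id=r["id"], name=r.get("name", ""),
                enzyme_species=r.get("enzyme"),
                reversible=bool(r["reversible"]), kcat=float(r["kcat"]),
                kcat_reverse=(float(r["kcat_reverse"])
                              if r.get("kcat_reverse") is not None else None),
                substrates=tuple((s["species"], int(s["stoichiometry"]))
                                 for s in r["substrates"]),
                products=tuple((s["species"], int(s["stoichiometry"]))
                               for s in r["products"]),
                km={k: float(v) for k, v in r.get("km", {}).items()})
            for r in d["reactions"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{where}: {exc}") from exc
    model = PathwayModel(species=species, reactions=reactions,
                         environment=env,
                         provenance=d.get("provenance", "fixture"))
    model.validate(strict=False)
    return model


def _model_to_xml(model: PathwayModel) -> ET.Element:
    d = _model_to_dict(model)
    root = ET.Element("pathway-model", version=FORMAT_VERSION,
                      provenance=model.provenance)
    ET.SubElement(root, "environment", {
        k: _fmt(v) for k, v in d["environment"].items()})
    for s in d["species"]:
        ET.SubElement(root, "species", {
            "id": s["id"], "name": s["name"], "role": s["role"],
            "molecular-weight": _fmt(s["molecular_weight"]),
            "initial-concentration": _fmt(s["initial_concentration"]),
            "approx": "true" if s["approx"] else "false"})
    for r in d["reactions"]:
        attrs = {"id": r["id"], "name": r["name"],
                 "reversible": "true" if r["reversible"] else "false",
                 "kcat": _fmt(r["kcat"])}
        if r.get("enzyme"):
            attrs["enzyme"] = r["enzyme"]
        if "kcat_reverse" in r:
            attrs["kcat-reverse"] = _fmt(r["kcat_reverse"])
        el = ET.SubElement(root, "reaction", attrs)
        for s in r["substrates"]:
            ET.SubElement(el, "substrate", species=s["species"],
                          stoichiometry=str(s["stoichiometry"]))
        for s in r["products"]:
            ET.SubElement(el, "product", species=s["species"],
                          stoichiometry=str(s["stoichiometry"]))
        for sp, v in r.get("km", {}).items():
            ET.SubElement(el, "km", species=sp, value=_fmt(v))
    return root


def _model_from_xml(root: ET.Element, where: str) -> PathwayModel:
    if root.tag != "pathway-model":
        raise ModelFormatError(
            f"{where}: root element is <{root.tag}>, expected <pathway-model>")
    version = root.get("version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"{where}: /pathway-model/@version: unknown schema version "
            f"{version!r} (this build reads version {FORMAT_VERSION})")
    env_el = root.find("environment")
    if env_el is None:
        raise ModelFormatError(f"{where}: /pathway-model/environment missing")
    d: dict = {
        "format": FORMAT_NAME, "version": version,
        "provenance": root.get("provenance", "fixture"),
        "environment": {k: float(v) for k, v in env_el.attrib.items()},
        "species": [], "reactions": [],
    }
    for el in root.findall("species"):
        try:
            d["species"].append({
                "id": el.attrib["id"], "name": el.get("name", ""),
                "role": el.attrib["role"],
                "molecular_weight": float(el.attrib["molecular-weight"]),
                "initial_concentration":
                    float(el.attrib["initial-concentration"]),
                "approx": el.get("approx") == "true"})
        except KeyError as exc:
            raise ModelFormatError(
                f"{where}: species {el.get('id')!r}: missing {exc}") from exc
    for el in root.findall("reaction"):
        try:
            r = {
                "id": el.attrib["id"], "name": el.get("name", ""),
                "enzyme": el.get("enzyme"),
                "reversible": el.attrib["reversible"] == "true",
                "kcat": float(el.attrib["kcat"]),
                "substrates": [
                    {"species": s.attrib["species"],
                     "stoichiometry": int(s.get("stoichiometry", "1"))}
                    for s in el.findall("substrate")],
                "products": [
                    {"species": s.attrib["species"],
                     "stoichiometry": int(s.get("stoichiometry", "1"))}
                    for s in el.findall("product")],
                "km": {s.attrib["species"]: float(s.attrib["value"])
                       for s in el.findall("km")},
            }
            if el.get("kcat-reverse") is not None:
                r["kcat_reverse"] = float(el.attrib["kcat-reverse"])
        except KeyError as exc:
            raise ModelFormatError(
                f"{where}: reaction {el.get('id')!r}: missing {exc}") from exc
        d["reactions"].append(r)
    return _model_from_dict(d, where)


def write_model(model: PathwayModel, path: str | Path) -> None:
    """Write a model to the native format (``.yaml``/``.yml`` → YAML mirror,
    anything else → versioned XML).  Round-trips losslessly."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(_model_to_dict(model), sort_keys=False))
        return
    root = _model_to_xml(model)
    ET.indent(root)
    path.write_text(ET.tostring(root, encoding="unicode") + "\n")


def read_model(path: str | Path) -> PathwayModel:
    """Read a model written by :func:`write_model` (XML or YAML mirror)."""
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("<"):
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise ModelFormatError(f"{path}: {exc}") from exc
        return _model_from_xml(root, str(path))
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ModelFormatError(f"{path}: not a mapping document")
    return _model_from_dict(data, str(path))
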