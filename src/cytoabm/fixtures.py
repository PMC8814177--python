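"""Bundled pathway models: toys with known behaviour, the adapted glycolysis
network, and a random-pathway generator for fuzzing.

Every fixture is built programmatically, validates, and round-trips through
the native model format.  The glycolysis fixture reproduces the adapted
yeast network (fermentation, adenylate kinase, ATPase, UDP→UTP and glucose
transport excluded; hexokinase/glucokinase, phosphofructokinase and pyruvate
kinase irreversible) with all initial concentrations below 1 mmol/l; values
not printed in the source study are documented approximations, overridable
from a user-supplied table.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Mapping

import numpy as np

from .data import (ENZYME_CONCENTRATIONS, EXACT_CONCENTRATIONS,
                   INITIAL_CONCENTRATIONS, MOLECULAR_WEIGHTS,
                   TURNOVER_NUMBERS)
from .engine import BindingModel, SimulationConfig
from .model_io import (PathwayModel, ReactionSpec, SpeciesSpec,
                       concentration_to_count, count_to_concentration)
from .physics import EnvironmentParams

_ENV = EnvironmentParams()


def _conc_of_count(n: int) -> float:
    return count_to_concentration(n, _ENV.volume)


def toy_single_reaction(n_substrate: int = 500, kcat: float = 100.0,
                        distance: float | None = None,
                        seed: int = 0) -> tuple[PathwayModel, SimulationConfig]:
    """One enzyme copy, one irreversible reaction S → P.

    Enzyme weight gives a ≈25 Å sphere, the substrate ≈4 Å.  The default
    config uses the ``uniform`` binding law with a perception distance equal
    to the box side, so binding is never rate-limiting and the product rate
    approaches the Michaelis–Menten Vmax limit of kcat products per second.
    """
    if n_substrate < 1:
        raise ValueError("need at least one substrate molecule")
    env = _ENV
    if distance is None:
        distance = env.side
    species = (
        SpeciesSpec(id="E", name="enzyme", role="enzyme",
                    molecular_weight=54000.0,
                    initial_concentration=_conc_of_count(1)),
        SpeciesSpec(id="S", name="substrate", molecular_weight=220.0,
                    initial_concentration=_conc_of_count(n_substrate)),
        SpeciesSpec(id="P", name="product", molecular_weight=220.0,
                    initial_concentration=0.0),
    )
    reactions = (ReactionSpec(
        id="R1", name="turnover", enzyme_species="E",
        substrates=(("S", 1),), products=(("P", 1),),
        reversible=False, kcat=kcat),)
    model = PathwayModel(species=species, reactions=reactions,
                         environment=env, provenance="fixture")
    model.validate()
    config = SimulationConfig(
        binding=BindingModel(distance=distance, law="uniform"),
        duration=1.0, seed=seed, env=env)
    return model, config


def toy_reversible_pair(seed: int = 0,
                        reversible: bool = True,
                        n_each: int = 0,
                        n_a: int = 120,
                        ) -> tuple[PathwayModel, SimulationConfig]:
    """One enzyme interconverting A ↔ B with equal kcat both ways
    (a triose-phosphate-isomerase-like automaton exercising direction
    fixing).  ``reversible=False`` yields the A → B only variant."""
    env = _ENV
    species = (
        SpeciesSpec(id="E", name="isomerase", role="enzyme",
                    molecular_weight=27000.0,
                    initial_concentration=_conc_of_count(2)),
        SpeciesSpec(id="A", molecular_weight=170.0,
                    initial_concentration=_conc_of_count(n_a)),
        SpeciesSpec(id="B", molecular_weight=170.0,
                    initial_concentration=_conc_of_count(n_each)),
    )
    reactions = (ReactionSpec(
        id="RAB", name="isomerisation", enzyme_species="E",
        substrates=(("A", 1),), products=(("B", 1),),
        reversible=reversible, kcat=500.0, kcat_reverse=500.0),)
    model = PathwayModel(species=species, reactions=reactions,
                         environment=env, provenance="fixture")
    model.validate()
    config = SimulationConfig(
        binding=BindingModel(distance=env.side, law="uniform"),
        duration=1.0, seed=seed, env=env)
    return model, config


# --------------------------------------------------------------------------
# Glycolysis
# --------------------------------------------------------------------------

_GLYCOLYSIS_REACTIONS: tuple[tuple[str, tuple, tuple, bool], ...] = (
    # (enzyme, substrates, products, irreversible)
    ("HXK1", (("GLC", 1), ("ATP", 1)), (("G6P", 1), ("ADP", 1)), True),
    ("HXK2", (("GLC", 1), ("ATP", 1)), (("G6P", 1), ("ADP", 1)), True),
    ("GLK1", (("GLC", 1), ("ATP", 1)), (("G6P", 1), ("ADP", 1)), True),
    ("PGI1", (("G6P", 1),), (("F6P", 1),), False),
    ("PFK", (("F6P", 1), ("ATP", 1)), (("F16BP", 1), ("ADP", 1)), True),
    ("FBA1", (("F16BP", 1),), (("DHAP", 1), ("GAP", 1)), False),
    ("TPI1", (("DHAP", 1),), (("GAP", 1),), False),
    ("TDH1", (("GAP", 1), ("NAD", 1)), (("BPG", 1), ("NADH", 1)), False),
    ("TDH2", (("GAP", 1), ("NAD", 1)), (("BPG", 1), ("NADH", 1)), False),
    ("TDH3", (("GAP", 1), ("NAD", 1)), (("BPG", 1), ("NADH", 1)), False),
    ("PGK1", (("BPG", 1), ("ADP", 1)), (("P3G", 1), ("ATP", 1)), False),
    ("GPM1", (("P3G", 1),), (("P2G", 1),), False),
    ("ENO1", (("P2G", 1),), (("PEP", 1),), False),
    ("ENO2", (("P2G", 1),), (("PEP", 1),), False),
    ("CDC19", (("PEP", 1), ("ADP", 1)), (("PYR", 1), ("ATP", 1)), True),
    # glycerol branch
    ("GPD1", (("DHAP", 1), ("NADH", 1)), (("G3P", 1), ("NAD", 1)), True),
    ("RHR2", (("G3P", 1),), (("GLY", 1),), True),
    # trehalose branch
    ("PGM1", (("G6P", 1),), (("G1P", 1),), False),
    ("UGP1", (("G1P", 1), ("UTP", 1)), (("UDPG", 1),), True),
    ("TPS1", (("UDPG", 1), ("G6P", 1)), (("T6P", 1),), True),
    ("TPS2", (("T6P", 1),), (("TRH", 1),), True),
    # glycogen branch
    ("GSY2", (("UDPG", 1),), (("GLYCOGEN", 1),), True),
)

#: full names for readability of the emitted model files
_NAMES = {
    "GLC": "glucose", "ATP": "ATP", "ADP": "ADP",
    "G6P": "glucose 6-phosphate", "F6P": "fructose 6-phosphate",
    "F16BP": "fructose 1,6-bisphosphate",
    "DHAP": "dihydroxyacetone phosphate",
    "GAP": "glyceraldehyde 3-phosphate", "NAD": "NAD+", "NADH": "NADH",
    "BPG": "1,3-bisphosphoglycerate", "P3G": "3-phosphoglycerate",
    "P2G": "2-phosphoglycerate", "PEP": "phosphoenolpyruvate",
    "PYR": "pyruvate", "G3P": "glycerol 3-phosphate", "GLY": "glycerol",
    "G1P": "glucose 1-phosphate", "UTP": "UTP", "UDPG": "UDP-glucose",
    "T6P": "trehalose 6-phosphate", "TRH": "trehalose",
    "GLYCOGEN": "glycogen",
}


def glycolysis_model(scale: float = 1.0,
                     concentration_overrides: Mapping[str, float] | None = None,
                     ) -> PathwayModel:
    """The adapted yeast glycolysis network, ready to simulate.

    ``scale`` multiplies every initial particle count (rounded, floored at 1
    per nonzero species) for desk-scale runs.  ``concentration_overrides``
    replaces default initial concentrations (mmol/l), e.g. with values
    transcribed from the source study's supplementary table.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    overrides = dict(concentration_overrides or {})
    env = _ENV
    volume = env.volume

    def scaled(c: float) -> float:
        full = concentration_to_count(c, volume)
        if full == 0:
            return 0.0
        n = max(1, int(round(scale * full)))
        return count_to_concentration(n, volume)

    species = []
    for sid in INITIAL_CONCENTRATIONS:
        c = overrides.get(sid, INITIAL_CONCENTRATIONS[sid])
        species.append(SpeciesSpec(
            id=sid, name=_NAMES[sid], role="metabolite",
            molecular_weight=MOLECULAR_WEIGHTS[sid],
            initial_concentration=scaled(c),
            approx=sid not in EXACT_CONCENTRATIONS and sid not in overrides))
    for eid, c in ENZYME_CONCENTRATIONS.items():
        species.append(SpeciesSpec(
            id=eid, name=eid, role="enzyme",
            molecular_weight=MOLECULAR_WEIGHTS[eid],
            initial_concentration=scaled(overrides.get(eid, c)),
            approx=eid not in overrides))
    reactions = []
    for enzyme, subs, prods, irreversible in _GLYCOLYSIS_REACTIONS:
        reactions.append(ReactionSpec(
            id=f"R_{enzyme}", name=f"reaction of {enzyme}",
            enzyme_species=enzyme, substrates=subs, products=prods,
            reversible=not irreversible,
            kcat=TURNOVER_NUMBERS[enzyme]))
    model = PathwayModel(
        species=tuple(species), reactions=tuple(reactions),
        environment=env, provenance="fixture:glycolysis")
    model.validate()
    return model


def glycolysis_config(distance: float, seed: int = 0,
                      duration: float = 1.0,
                      record_every: int = 100) -> SimulationConfig:
    """Study configuration for one force regime (d = 5, 10 or 300 Å)."""
    return SimulationConfig(
        binding=BindingModel(distance=distance, law="cubic"),
        duration=duration, seed=seed, record_every=record_every, env=_ENV)


# --------------------------------------------------------------------------
# Random pathways (fuzzing)
# --------------------------------------------------------------------------

def random_pathway(n_species: int = 6, n_reactions: int = 4,
                   seed: int = 0) -> PathwayModel:
    """Deterministic random connected pathway for stress tests.

    One enzyme per reaction; reaction i draws substrates from the pool and
    feeds its first product into the next reaction, so the network is
    connected; weights, kcats and concentrations are drawn from realistic
    ranges and every model validates.
    """
    if n_reactions < 1:
        raise ValueError("need at least one reaction")
    if n_species < 2:
        raise ValueError("need at least two metabolite species")
    rng = np.random.default_rng(seed)
    mets = [f"M{i}" for i in range(n_species)]
    species = [
        SpeciesSpec(
            id=m, role="metabolite",
            molecular_weight=float(rng.uniform(100, 700)),
            initial_concentration=float(
                _conc_of_count(int(rng.integers(5, 60)))))
        for m in mets
    ]
    reactions = []
    for i in range(n_reactions):
        eid = f"E{i}"
        species.append(SpeciesSpec(
            id=eid, role="enzyme",
            molecular_weight=float(rng.uniform(2e4, 2e5)),
            initial_concentration=_conc_of_count(int(rng.integers(1, 4)))))
        # chain connectivity: substrate of reaction i is product of i-1
        first_sub = mets[i % n_species]
        pool = [m for m in mets if m != first_sub]
        subs = [(first_sub, 1)]
        if rng.random() < 0.4:
            extra = pool[int(rng.integers(len(pool)))]
            subs.append((extra, int(rng.integers(1, 3))))
        sub_ids = {s for s, _ in subs}
        prod_pool = [m for m in mets if m not in sub_ids]
        if not prod_pool:
            prod_pool = [mets[(i + 1) % n_species]]
        prods = [(mets[(i + 1) % n_species]
                  if mets[(i + 1) % n_species] in prod_pool
                  else prod_pool[0], 1)]
        if rng.random() < 0.3 and len(prod_pool) > 1:
            prods.append((prod_pool[int(rng.integers(len(prod_pool)))],
                          int(rng.integers(1, 3))))
        reactions.append(ReactionSpec(
            id=f"R{i}", enzyme_species=eid,
            substrates=tuple(subs), products=tuple(prods),
            reversible=bool(rng.random() < 0.4),
            kcat=float(rng.uniform(10, 1000))))
    model = PathwayModel(species=tuple(species), reactions=tuple(reactions),
                         environment=_ENV,
                         provenance=f"fixture:random:{seed}")
    model.validate()
    return model


#: name -> callable returning a PathwayModel (catalog for the CLI)
CATALOG: dict[str, Callable[..., PathwayModel]] = {
    "glycolysis": glycolysis_model,
    "toy-single": lambda **kw: toy_single_reaction(**kw)[0],
    "toy-reversible": lambda **kw: toy_reversible_pair(**kw)[0],
    "random": random_pathway,
}
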