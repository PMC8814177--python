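import numpy as np
import pytest

from cytoabm import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def glycolysis():
    return fixtures.glycolysis_model()


SBML_HEADER = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
<model id="mini_glycolysis" substanceUnits="substance">
<listOfUnitDefinitions>
<unitDefinition id="substance"><listOfUnits>
<unit kind="mole" scale="-3" multiplier="1" exponent="1"/>
</listOfUnits></unitDefinition>
</listOfUnitDefinitions>
<listOfCompartments><compartment id="cell" size="1" constant="true"/></listOfCompartments>
"""


def sbml_species(sid, conc=None):
    conc_attr = f' initialConcentration="{conc}"' if conc is not None else ""
    return (f'<species id="{sid}" compartment="cell"{conc_attr}'
            ' hasOnlySubstanceUnits="false" boundaryCondition="false"'
            ' constant="false"/>')


def sbml_reaction(rid, reactants, products, modifier=None, reversible=False,
                  kcat=None):
    parts = [f'<reaction id="{rid}" reversible="{str(reversible).lower()}"'
             ' fast="false">']
    parts.append("<listOfReactants>")
    for sp in reactants:
        parts.append(f'<speciesReference species="{sp}" stoichiometry="1"'
                     ' constant="true"/>')
    parts.append("</listOfReactants><listOfProducts>")
    for sp in products:
        parts.append(f'<speciesReference species="{sp}" stoichiometry="1"'
                     ' constant="true"/>')
    parts.append("</listOfProducts>")
    if modifier:
        parts.append(f'<listOfModifiers><modifierSpeciesReference '
                     f'species="{modifier}"/></listOfModifiers>')
    if kcat is not None:
        parts.append(
            '<kineticLaw>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            '<ci> kcat </ci></math>'
            '<listOfLocalParameters>'
            f'<localParameter id="kcat" value="{kcat}"/>'
            '</listOfLocalParameters></kineticLaw>')
    parts.append("</reaction>")
    return "".join(parts)


@pytest.fixture
def mini_sbml(tmp_path):
    """A small synthetic SBML model (two glycolysis-like reactions)."""
    text = (
        SBML_HEADER
        + "<listOfSpecies>"
        + sbml_species("GLC", 6.28)
        + sbml_species("ATP", 4.29)
        + sbml_species("ADP", 1.28)
        + sbml_species("G6P", 0.68)
        + sbml_species("F6P", 0.12)
        + sbml_species("HXK1", 0.01)
        + sbml_species("PGI1", 0.02)
        + "</listOfSpecies><listOfReactions>"
        + sbml_reaction("R_HXK1", ["GLC", "ATP"], ["G6P", "ADP"],
                        modifier="HXK1", reversible=True, kcat=200.0)
        + sbml_reaction("R_PGI1", ["G6P"], ["F6P"], modifier="PGI1",
                        reversible=True, kcat=900.0)
        + "</listOfReactions></model></sbml>"
    )
    path = tmp_path / "mini.sbml"
    path.write_text(text)
    return path
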